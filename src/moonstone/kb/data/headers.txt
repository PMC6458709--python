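History of Present Illness
Chief Complaint
Past Medical History
Social History
Social Work Note
Family History
Review of Systems
Physical Exam
Assessment
Plan
Assessment and Plan
Hospital Course
Medications
Discharge Summary
Disposition
Nursing Assessment
Living Situation
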