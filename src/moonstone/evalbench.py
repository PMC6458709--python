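"""Headless evaluation workbench: span matching and the metric panel.

Gold and system annotation sets over the same documents are matched
one-to-one per class (greedily, largest span overlap first), giving
per-class TP/FP/FN counts; from those the panel computes sensitivity
(recall), PPV (precision) and F-score, with NPV and accuracy available
only when an explicit TN count is supplied — mention-level TN is not
derivable from annotations alone.

Metric display defaults to *truncation* at two decimals rather than
rounding: the published benchmark panel for this task is consistent with
truncation (e.g. PPV 79/118 = 0.6694 printed as 0.66), and the exact
unrounded values are always retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "match_annotations",
    "compute_metrics",
    "table_report",
    "REFERENCE_COUNTS",
    "REFERENCE_CLASS_ORDER",
]

# Published mention-level benchmark counts for the seven social-risk
# classes (original system, VA evaluation corpus): class -> (TP, FP, FN).
# These are inputs for reproducing the derived metric columns; the corpus
# itself is restricted and is not part of this package.
REFERENCE_CLASS_ORDER = [
    "Homeless/marginally housed",
    "Lives at home/not homeless",
    "Lives in a facility",
    "Does not live alone",
    "Lives alone",
    "Has social support",
    "No social support",
]
REFERENCE_COUNTS = {
    "Homeless/marginally housed": (79, 39, 11),
    "Lives at home/not homeless": (6382, 111, 335),
    "Lives in a facility": (426, 131, 141),
    "Does not live alone": (1329, 123, 88),
    "Lives alone": (710, 19, 17),
    "Has social support": (5174, 525, 337),
    "No social support": (220, 59, 19),
}


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: Optional[int] = None

    def __post_init__(self):
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be non-negative")


@dataclass
class MetricReport:
    """Per-class metrics; ``None`` marks an undefined metric (empty
    denominator), which is *not* the same as zero."""

    sensitivity: Optional[float]
    ppv: Optional[float]
    f_score: Optional[float]
    npv: Optional[float] = None
    accuracy: Optional[float] = None
    exact: dict = field(default_factory=dict)  # unrounded Fractions
    rounding_mode: str = "truncate"
    decimals: int = 2


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def match_annotations(gold: Sequence, system: Sequence, criterion: str = "exact_span"):
    """Greedy one-to-one matching of gold vs system annotations.

    Each annotation carries (doc_id, start, end, class_label).  A pair can
    match only within the same document and class; ``exact_span`` requires
    identical offsets, ``any_overlap`` a positive overlap.  Ties resolve
    toward the largest overlap, then the earliest spans.  Returns a dict
    class -> :class:`ConfusionCounts`.
    """
    if criterion not in ("exact_span", "any_overlap"):
        raise ValueError(f"unknown criterion {criterion!r}")
    gold_docs = {a.doc_id for a in gold}
    counts: dict[str, ConfusionCounts] = {}

    def bucket(cls: str) -> ConfusionCounts:
        return counts.setdefault(cls, ConfusionCounts())

    for a in system:
        if gold and a.doc_id not in gold_docs and not _known_doc(a.doc_id, gold, system):
            raise ValueError(f"system annotation references unknown document {a.doc_id!r}")

    keys = sorted(
        {(a.doc_id, a.class_label) for a in gold} | {(a.doc_id, a.class_label) for a in system}
    )
    for doc_id, cls in keys:
        g = [a for a in gold if a.doc_id == doc_id and a.class_label == cls]
        s = [a for a in system if a.doc_id == doc_id and a.class_label == cls]
        pairs = []
        for gi, ga in enumerate(g):
            for si, sa in enumerate(s):
                ov = _overlap(ga.start, ga.end, sa.start, sa.end)
                if criterion == "exact_span":
                    if (ga.start, ga.end) == (sa.start, sa.end):
                        pairs.append((-(ga.end - ga.start), ga.start, sa.start, gi, si))
                elif ov > 0:
                    pairs.append((-ov, ga.start, sa.start, gi, si))
        pairs.sort()
        used_g: set[int] = set()
        used_s: set[int] = set()
        matched = 0
        for _, _, _, gi, si in pairs:
            if gi in used_g or si in used_s:
                continue
            used_g.add(gi)
            used_s.add(si)
            matched += 1
        b = bucket(cls)
        b.tp += matched
        b.fp += len(s) - matched
        b.fn += len(g) - matched
    return counts


def _known_doc(doc_id, gold, system) -> bool:
    # a document with only system annotations is legitimate (pure FPs)
    return any(a.doc_id == doc_id for a in system)


def _format(value: Fraction, decimals: int, mode: str) -> float:
    scale = 10**decimals
    if mode == "truncate":
        return math.floor(value * scale) / scale
    if mode == "round":
        # round half up on the exact rational, not on a float
        return math.floor(value * scale + Fraction(1, 2)) / scale
    raise ValueError(f"unknown rounding mode {mode!r}")


def compute_metrics(
    counts: ConfusionCounts, decimals: int = 2, mode: str = "truncate"
) -> MetricReport:
    """Sensitivity, PPV, F (and NPV/accuracy given TN) from counts.

    All ratios are computed exactly (rational arithmetic); the F-score is
    the harmonic mean of the *unrounded* PPV and sensitivity; display
    values are then truncated or rounded to *decimals*.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    exact: dict[str, Fraction] = {}
    sens = Fraction(tp, tp + fn) if tp + fn > 0 else None
    ppv = Fraction(tp, tp + fp) if tp + fp > 0 else None
    if sens is not None:
        exact["sensitivity"] = sens
    if ppv is not None:
        exact["ppv"] = ppv
    f = None
    if sens is not None and ppv is not None and (sens + ppv) > 0:
        f = 2 * ppv * sens / (ppv + sens)
        exact["f_score"] = f
    npv = acc = None
    if tn is not None:
        if tn + fn > 0:
            npv = Fraction(tn, tn + fn)
            exact["npv"] = npv
        if tp + tn + fp + fn > 0:
            acc = Fraction(tp + tn, tp + tn + fp + fn)
            exact["accuracy"] = acc
    fmt = lambda v: None if v is None else _format(v, decimals, mode)
    return MetricReport(
        sensitivity=fmt(sens),
        ppv=fmt(ppv),
        f_score=fmt(f),
        npv=fmt(npv),
        accuracy=fmt(acc),
        exact=exact,
        rounding_mode=mode,
        decimals=decimals,
    )


def table_report(
    gold_dir,
    system_dir,
    criterion: str = "exact_span",
    mode: str = "truncate",
    class_labels: Optional[Sequence[str]] = None,
) -> str:
    """Per-class counts and metrics over two directories of eHOST XML.

    Expects ``<doc_id>.txt`` documents next to ``<doc_id>.xml`` annotation
    files in each directory (documents are only needed on the gold side).
    Returns a TSV with one row per class plus a micro-average row.
    """
    import pandas as pd

    from .pipeline import read_ehost_xml
    from .textproc import RawDocument

    def load_side(path) -> list:
        out = []
        for xml_file in sorted(Path(path).glob("*.xml")):
            doc_id = xml_file.stem
            txt = _find_doc_text(Path(gold_dir), Path(system_dir), doc_id)
            doc = RawDocument(doc_id, txt)
            anns, _ = read_ehost_xml(xml_file.read_text(), doc)
            out.extend(anns)
        return out

    gold = load_side(gold_dir)
    system = load_side(system_dir)
    counts = match_annotations(gold, system, criterion)
    labels = list(class_labels) if class_labels else sorted(
        set(counts) | set(a.class_label for a in gold + system)
    )
    rows = []
    total = ConfusionCounts()
    for cls in labels:
        c = counts.get(cls, ConfusionCounts())
        total.tp += c.tp
        total.fp += c.fp
        total.fn += c.fn
        rows.append(_metric_row(cls, c, mode))
    rows.append(_metric_row("MICRO_AVERAGE", total, mode))
    df = pd.DataFrame(rows, columns=["class", "tp", "fp", "fn", "sensitivity", "ppv", "f_score"])
    return df.to_csv(sep="\t", index=False)


def _metric_row(cls: str, c: ConfusionCounts, mode: str) -> dict:
    m = compute_metrics(c, mode=mode)
    return {
        "class": cls,
        "tp": c.tp,
        "fp": c.fp,
        "fn": c.fn,
        "sensitivity": m.sensitivity,
        "ppv": m.ppv,
        "f_score": m.f_score,
    }


def _find_doc_text(gold_dir: Path, system_dir: Path, doc_id: str) -> str:
    for d in (gold_dir, system_dir):
        p = d / f"{doc_id}.txt"
        if p.exists():
            return p.read_text()
    return ""
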