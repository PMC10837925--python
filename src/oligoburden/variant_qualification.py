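"""Qualifying-variant filters and consequence classification.

A variant qualifies for burden counting when it clears, with strict
inequalities, a read-depth floor (> 20 reads), a rarity ceiling
(minor allele frequency < 5% in every reference population where it is
observed), and, per consequence class, an in-silico deleteriousness gate
(REVEL > 0.5 for missense; splice-impact or splicing-consensus score > 0.6
for splice-site variants). Loss-of-function consequences other than splice
sites (frameshift, stop gain/loss, start loss) qualify on consequence
alone. Variants in neither class never qualify.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .cohort_data import VariantRecord

LOF = "LOF"
MISSENSE = "missense"
OTHER = "other"

# Annotation-string synonyms, matched case-insensitively after stripping
# separators. Covers Sequence Ontology and ANNOVAR spellings.
_LOF_TOKENS = {
    "frameshift", "frameshiftvariant", "frameshiftinsertion", "frameshiftdeletion",
    "frameshiftsubstitution", "stopgain", "stopgained", "stoploss", "stoplost",
    "startloss", "startlost", "splicesite", "splicing", "splicedonorvariant",
    "spliceacceptorvariant", "splicedonor", "spliceacceptor",
}
_MISSENSE_TOKENS = {"missense", "missensevariant", "nonsynonymoussnv", "nonsynonymous"}


def _canon(consequence: str) -> str:
    return "".join(ch for ch in consequence.lower() if ch.isalnum())


def classify_consequence(consequence: str) -> str:
    """Map an annotation string to LOF / missense / other.

    Loss-of-function covers frameshift, splice-site and stop (plus stop-loss
    and start-loss) consequences; anything unrecognised is "other".
    """
    if not consequence:
        raise ValueError("empty consequence string")
    canon = _canon(consequence)
    if canon in _LOF_TOKENS:
        return LOF
    if canon in _MISSENSE_TOKENS:
        return MISSENSE
    # composite annotations like "splice_donor_variant&intron_variant"
    if "splic" in canon and any(t in canon for t in ("donor", "acceptor", "site", "splicing")):
        return LOF
    return OTHER


def is_splice(consequence: str) -> bool:
    """Whether a consequence string denotes a splice-site (splice-class) variant."""
    return "splic" in consequence.lower()


@dataclass(frozen=True)
class QualificationConfig:
    """Filter thresholds; all comparisons are strict (boundary values fail)."""

    min_depth_exclusive: int = 20
    max_maf_exclusive: float = 0.05
    min_revel_exclusive: float = 0.5
    min_splice_exclusive: float = 0.6
    min_scsnv_exclusive: float = 0.6
    splice_scores_conjunctive: bool = False  # True: require BOTH splice scores
    count_het_only: bool = True

    def __post_init__(self) -> None:
        if self.min_depth_exclusive < 0:
            raise ValueError("min_depth_exclusive must be nonnegative")
        for name in ("max_maf_exclusive", "min_revel_exclusive",
                     "min_splice_exclusive", "min_scsnv_exclusive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class QualificationResult:
    retained: bool
    consequence_class: str
    reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.retained != (len(self.reasons) == 0):
            raise ValueError("retained must hold exactly when reasons is empty")


def qualify(v: VariantRecord, cfg: QualificationConfig | None = None) -> QualificationResult:
    """Apply all filters to one variant; reasons list every failed filter.

    Missing population frequencies never disqualify (a variant absent from
    all reference panels is treated as rare); a missing score required by
    the variant's class does disqualify it, since deleteriousness cannot be
    established. Depth is mandatory.
    """
    cfg = cfg or QualificationConfig()
    if v.depth is None:
        raise ValueError(f"variant {v.chrom}:{v.pos} has no read depth (mandatory field)")
    cls = classify_consequence(v.consequence)
    reasons: list[str] = []
    if not v.depth > cfg.min_depth_exclusive:
        reasons.append("depth")
    if any(af >= cfg.max_maf_exclusive for af in v.population_afs):
        reasons.append("maf")
    if cls == MISSENSE:
        if v.revel is None or not v.revel > cfg.min_revel_exclusive:
            reasons.append("revel")
    elif cls == LOF and is_splice(v.consequence):
        ss_ok = v.splice_score is not None and v.splice_score > cfg.min_splice_exclusive
        sc_ok = v.scsnv is not None and v.scsnv > cfg.min_scsnv_exclusive
        ok = (ss_ok and sc_ok) if cfg.splice_scores_conjunctive else (ss_ok or sc_ok)
        if not ok:
            reasons.append("splice_score")
    elif cls == OTHER:
        reasons.append("class")
    return QualificationResult(
        retained=not reasons, consequence_class=cls, reasons=tuple(reasons)
    )


@dataclass
class QualificationSummary:
    """Input/retained tallies by consequence class plus failure-reason counts."""

    total: int
    input_by_class: Counter
    retained_by_class: Counter
    failure_reasons: Counter

    @property
    def n_retained(self) -> int:
        return sum(self.retained_by_class.values())


def qualify_all(
    tuples: Iterable[tuple[str, VariantRecord]],
    cfg: QualificationConfig | None = None,
) -> tuple[list[tuple[str, VariantRecord]], QualificationSummary]:
    """Filter carrier tuples; returns (retained tuples, summary).

    The class tallies partition the input; a variant failing several
    filters contributes to every corresponding reason count.
    """
    cfg = cfg or QualificationConfig()
    retained: list[tuple[str, VariantRecord]] = []
    input_by_class: Counter = Counter()
    retained_by_class: Counter = Counter()
    failure_reasons: Counter = Counter()
    total = 0
    for sid, rec in tuples:
        total += 1
        res = qualify(rec, cfg)
        input_by_class[res.consequence_class] += 1
        if res.retained:
            retained.append((sid, rec))
            retained_by_class[res.consequence_class] += 1
        else:
            failure_reasons.update(res.reasons)
    return retained, QualificationSummary(
        total=total,
        input_by_class=input_by_class,
        retained_by_class=retained_by_class,
        failure_reasons=failure_reasons,
    )
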