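"""Classification rules for the two confirmatory assays and truth resolution.

Activity: the G6PD/6PGD ratio is called deficient strictly below the
cutoff (default 1.0, per the approved kit).  Panel genotyping: positive
iff at least one variant in the 12-variant target set is detected —
variants outside the panel are invisible to it.  Carrier truth: the
panel is assumed fully concordant with Sanger sequencing on its target
variants, so an infant is a carrier iff the panel or Sanger sequencing
found a pathogenic variant; truth is undefined for panel-negative
infants who were never sequenced.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import (
    DEFAULT_PANEL,
    CarrierStatus,
    CohortTable,
    InfantRecord,
    PanelDefinition,
    VariantCall,
)

__all__ = [
    "ActivityCall",
    "PanelCall",
    "IndeterminateTruthError",
    "classify_activity",
    "panel_call",
    "resolve_truth",
    "cohort_truths",
]


class IndeterminateTruthError(ValueError):
    """Carrier truth cannot be resolved (panel-negative, never sequenced)."""


@dataclass(frozen=True)
class ActivityCall:
    status: str  # "deficient" | "normal"
    ratio: float
    cutoff: float = 1.0

    @property
    def deficient(self) -> bool:
        return self.status == "deficient"


@dataclass(frozen=True)
class PanelCall:
    status: str  # "positive" | "negative"
    detected: tuple[VariantCall, ...] = ()

    @property
    def positive(self) -> bool:
        return self.status == "positive"


def classify_activity(ratio: float, cutoff: float = 1.0) -> ActivityCall:
    """Call an activity ratio deficient (< cutoff) or normal (>= cutoff)."""
    if ratio < 0:
        raise ValueError(f"activity ratio must be >= 0, got {ratio}")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    status = "deficient" if ratio < cutoff else "normal"
    return ActivityCall(status=status, ratio=ratio, cutoff=cutoff)


def panel_call(
    variants: tuple[VariantCall, ...], panel: PanelDefinition = DEFAULT_PANEL
) -> PanelCall:
    """Targeted genotyping call: positive iff any detected variant is on-panel."""
    detected = tuple(v for v in variants if v.cdna in panel)
    return PanelCall(status="positive" if detected else "negative", detected=detected)


def resolve_truth(record: InfantRecord) -> CarrierStatus:
    """Resolve carrier truth from panel and gold-standard sequencing results.

    Panel-positive infants are carriers without consulting Sanger (the
    panel's calls are taken as fully concordant with sequencing).
    Panel-negative infants require a Sanger result.
    """
    if record.panel_positive:
        return CarrierStatus.CARRIER
    if record.sanger_result is None:
        raise IndeterminateTruthError(
            f"record {record.id}: panel-negative and never sequenced — "
            f"carrier truth undefined"
        )
    if record.sanger_positive:
        return CarrierStatus.CARRIER
    return CarrierStatus.NON_CARRIER


def cohort_truths(cohort: CohortTable) -> dict[str, CarrierStatus]:
    """Resolve truth for every record, failing fast with all offending ids."""
    truths: dict[str, CarrierStatus] = {}
    bad: list[str] = []
    for r in cohort:
        try:
            truths[r.id] = resolve_truth(r)
        except IndeterminateTruthError:
            bad.append(r.id)
    if bad:
        raise IndeterminateTruthError(
            f"{len(bad)} record(s) with indeterminate carrier truth "
            f"(panel-negative, not sequenced): {bad[:10]}"
        )
    return truths
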