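"""Instrument selection: significance thresholding with fallback, greedy LD
clumping, outcome-association filtering, instrument strength (F), per-SNP
variance explained, Steiger directionality filtering, and the composed
pipeline with a full audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .errors import EmptyOverlapError, MissingLDError, NoInstrumentError
from .mr_estimators import variance_explained
from .mr_presso import PressoResult, presso
from .sumstats_io import GwasPanel, HarmonisedSet, VariantAssociation, harmonise
from .synthetic_gwas import LDMatrix


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds for the six-stage instrument-selection pipeline."""

    p_primary: float = 5e-8
    p_fallback: float = 5e-5
    min_snps_for_primary: int = 5
    clump_window_kb: int = 500
    clump_r2: float = 0.01
    p_outcome_min: float = 0.05
    f_min: float = 10.0
    steiger_filter: bool = True

    def __post_init__(self):
        if self.p_fallback < self.p_primary:
            raise ValueError("p_fallback must be >= p_primary")
        if not 0.0 < self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must be in (0, 1]")


#: Named parameter profiles.  "bloodcell" uses the wide-window strict-r2
#: clumping preset; "reverse_mr" additionally tightens the significance
#: threshold to 1e-8 with no fallback.
PROFILES: dict[str, SelectionParams] = {
    "default": SelectionParams(),
    "bloodcell": SelectionParams(clump_window_kb=10_000, clump_r2=0.001),
    "reverse_mr": SelectionParams(
        p_primary=1e-8,
        p_fallback=1e-8,
        min_snps_for_primary=0,
        clump_window_kb=10_000,
        clump_r2=0.001,
    ),
}


class AuditEntry(NamedTuple):
    snp_id: str
    stage_removed: str
    reason: str


@dataclass(frozen=True)
class InstrumentSet:
    """Final instruments plus per-SNP strength statistics and audit trail."""

    harmonised: HarmonisedSet
    f_stat: np.ndarray
    r2_exp: np.ndarray
    r2_out: np.ndarray
    audit: tuple[AuditEntry, ...]
    threshold_used: float
    presso: PressoResult | None = None


def threshold_instruments(
    exposure: GwasPanel, params: SelectionParams
) -> tuple[GwasPanel, float]:
    """Keep genome-wide-significant SNPs, falling back to the looser threshold
    when fewer than ``min_snps_for_primary`` survive.

    Returns the filtered panel and the threshold actually used.
    """
    primary = [r for r in exposure if r.pval < params.p_primary]
    if len(primary) >= params.min_snps_for_primary and primary:
        return exposure.subset(r.snp_id for r in primary), params.p_primary
    fallback = [r for r in exposure if r.pval < params.p_fallback]
    if not fallback:
        raise NoInstrumentError(
            f"no SNP in {exposure.trait_id!r} passes p < {params.p_fallback}",
            stage="threshold",
        )
    return exposure.subset(r.snp_id for r in fallback), params.p_fallback


def clump(panel: GwasPanel, ld: LDMatrix, window_kb: int, r2_max: float) -> GwasPanel:
    """Greedy LD clumping.

    Repeatedly keep the remaining SNP with the smallest p-value (ties broken
    by snp_id) and discard remaining SNPs on the same chromosome within
    ``window_kb`` whose r2 with it exceeds ``r2_max``.  Output preserves the
    input panel's row order and is independent of it.
    """
    missing = [r.snp_id for r in panel if not ld.has(r.snp_id)]
    if missing:
        raise MissingLDError(f"SNPs absent from LD matrix: {missing}")
    order = sorted(panel.records, key=lambda r: (r.pval, r.snp_id))
    kept: set[str] = set()
    discarded: set[str] = set()
    for lead in order:
        if lead.snp_id in discarded:
            continue
        kept.add(lead.snp_id)
        for other in order:
            if other.snp_id in kept or other.snp_id in discarded:
                continue
            if (
                other.chrom == lead.chrom
                and abs(other.pos - lead.pos) <= window_kb * 1000
                and ld.r2_between(lead.snp_id, other.snp_id) > r2_max
            ):
                discarded.add(other.snp_id)
    return panel.subset(kept)


def filter_outcome_association(
    candidates: GwasPanel, outcome: GwasPanel, p_min: float
) -> GwasPanel:
    """Drop candidates significantly associated with the outcome
    (outcome-panel p <= ``p_min``).

    Candidates absent from the outcome panel pass this stage; harmonisation
    drops them later with reason ``missing_in_outcome``.  ``p_min = 0``
    disables the filter.
    """
    kept = []
    for r in candidates:
        o = outcome.get(r.snp_id)
        if o is not None and o.pval <= p_min:
            continue
        kept.append(r.snp_id)
    if not kept:
        raise NoInstrumentError(
            "every candidate is associated with the outcome", stage="outcome_filter"
        )
    return candidates.subset(kept)


def f_statistic(record: VariantAssociation) -> float:
    """Single-SNP instrument-strength F statistic, ``(beta/se)^2``."""
    return (record.beta / record.se) ** 2


def snp_r2(record: VariantAssociation) -> float:
    """Per-SNP trait variance explained, ``t^2/(t^2 + n - 2)``."""
    return float(variance_explained(record.beta, record.se, record.n))


def steiger_filter(hset: HarmonisedSet) -> tuple[HarmonisedSet, tuple[AuditEntry, ...]]:
    """Remove SNPs explaining strictly more outcome than exposure variance."""
    r2_exp = variance_explained(hset.beta_exp, hset.se_exp, hset.n_exp)
    r2_out = variance_explained(hset.beta_out, hset.se_out, hset.n_out)
    bad = r2_out > r2_exp
    audit = tuple(
        AuditEntry(s, "steiger", "steiger_reversed")
        for s, b in zip(hset.snp_ids, bad)
        if b
    )
    if not bad.any():
        return hset, ()
    kept = [s for s, b in zip(hset.snp_ids, bad) if not b]
    if not kept:
        raise NoInstrumentError("Steiger filter removed every SNP", stage="steiger")
    return hset.subset(kept), audit


def select_instruments(
    exposure: GwasPanel,
    outcome: GwasPanel,
    ld: LDMatrix,
    params: SelectionParams,
    *,
    run_presso: bool = True,
    presso_n_sim: int = 2000,
    presso_outlier_alpha: float = 0.05,
    presso_global_alpha: float = 0.05,
    presso_seed: int = 0,
    palindrome_eaf_window: float = 0.08,
) -> InstrumentSet:
    """Compose the full selection pipeline.

    Stage order: significance threshold -> LD clump -> outcome-association
    filter -> harmonise -> F filter -> Steiger filter -> iterated MR-PRESSO
    outlier pruning (until global p exceeds ``presso_global_alpha``, no
    outliers are flagged, or fewer than 4 SNPs remain).  Every removed SNP
    appears exactly once in the audit trail.
    """
    audit: list[AuditEntry] = []

    thresholded, threshold_used = threshold_instruments(exposure, params)
    surviving = set(thresholded.snp_ids)
    audit += [
        AuditEntry(r.snp_id, "threshold", "above_p_threshold")
        for r in exposure
        if r.snp_id not in surviving
    ]

    clumped = clump(thresholded, ld, params.clump_window_kb, params.clump_r2)
    surviving = set(clumped.snp_ids)
    audit += [
        AuditEntry(s, "clump", "ld_with_better_snp")
        for s in thresholded.snp_ids
        if s not in surviving
    ]

    filtered = filter_outcome_association(clumped, outcome, params.p_outcome_min)
    surviving = set(filtered.snp_ids)
    audit += [
        AuditEntry(s, "outcome_filter", "outcome_associated")
        for s in clumped.snp_ids
        if s not in surviving
    ]

    try:
        hset = harmonise(filtered, outcome, palindrome_eaf_window)
    except EmptyOverlapError as exc:
        raise NoInstrumentError(str(exc), stage="harmonise") from exc
    audit += [AuditEntry(s, "harmonise", reason) for s, reason in hset.dropped]

    f_all = (hset.beta_exp / hset.se_exp) ** 2
    weak = f_all <= params.f_min
    if weak.any():
        audit += [
            AuditEntry(s, "f_filter", "weak_instrument")
            for s, b in zip(hset.snp_ids, weak)
            if b
        ]
        kept = [s for s, b in zip(hset.snp_ids, weak) if not b]
        if not kept:
            raise NoInstrumentError("all instruments are weak (F <= f_min)", stage="f_filter")
        hset = hset.subset(kept)

    if params.steiger_filter:
        hset, steiger_audit = steiger_filter(hset)
        audit += list(steiger_audit)

    presso_result: PressoResult | None = None
    while run_presso and hset.n_snp >= 4:
        presso_result = presso(
            hset,
            n_sim=presso_n_sim,
            outlier_alpha=presso_outlier_alpha,
            seed=presso_seed,
        )
        if presso_result.global_p > presso_global_alpha or not presso_result.outliers:
            break
        audit += [AuditEntry(s, "presso", "presso_outlier") for s in presso_result.outliers]
        kept = [s for s in hset.snp_ids if s not in presso_result.outliers]
        if not kept:
            raise NoInstrumentError("MR-PRESSO flagged every SNP", stage="presso")
        hset = hset.subset(kept)
        if hset.n_snp < 3:
            break

    return InstrumentSet(
        harmonised=hset,
        f_stat=(hset.beta_exp / hset.se_exp) ** 2,
        r2_exp=variance_explained(hset.beta_exp, hset.se_exp, hset.n_exp),
        r2_out=variance_explained(hset.beta_out, hset.se_out, hset.n_out),
        audit=tuple(audit),
        threshold_used=threshold_used,
        presso=presso_result,
    )


def exposure_side_instruments(
    exposure: GwasPanel, ld: LDMatrix, params: SelectionParams
) -> tuple[GwasPanel, float]:
    """Exposure-only selection (threshold, clump, F) with no outcome in play.

    Used when the same exposure's instruments must be re-used against several
    secondary traits (e.g. the mediator leg of a two-step analysis).
    """
    panel, threshold_used = threshold_instruments(exposure, params)
    panel = clump(panel, ld, params.clump_window_kb, params.clump_r2)
    strong = [r.snp_id for r in panel if f_statistic(r) > params.f_min]
    if not strong:
        raise NoInstrumentError("all instruments are weak (F <= f_min)", stage="f_filter")
    return panel.subset(strong), threshold_used


def audit_to_tsv(audit: tuple[AuditEntry, ...], path) -> None:
    """Write an audit trail as a three-column TSV."""
    lines = ["snp_id\tstage_removed\treason"]
    lines += [f"{a.snp_id}\t{a.stage_removed}\t{a.reason}" for a in audit]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
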