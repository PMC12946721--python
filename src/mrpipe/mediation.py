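"""Two-step MR mediation decomposition with delta-method uncertainty.

The indirect (mediated) effect is the product of the univariable
exposure-on-mediator estimate beta_a and the exposure-adjusted
mediator-on-outcome estimate beta_b from multivariable IVW:

* indirect  = beta_a * beta_b
* direct    = total - indirect
* proportion = indirect / total

The indirect effect's 95% CI and two-sided p come from the first-order
delta (Sobel) variance ``beta_a^2 se_b^2 + beta_b^2 se_a^2``; a second-order
term ``se_a^2 se_b^2`` is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import EmptyOverlapError, MRPipeError, NoInstrumentError
from .iv_selection import SelectionParams, exposure_side_instruments, select_instruments
from .mr_estimators import Z95, MREstimate, ivw
from .mvmr import build_mvmr_input, mvmr_ivw
from .sumstats_io import GwasPanel, harmonise
from .synthetic_gwas import LDMatrix

CLASSIFICATIONS = ("complete", "partial", "none", "inconsistent")


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of one exposure -> mediator -> outcome triple."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    total: float
    se_total: float
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    indirect: float
    se_indirect: float
    ci_low: float
    ci_high: float
    direct: float
    proportion: float  # signed; NaN when total == 0
    proportion_abs: float
    pval: float
    classification: str
    alpha: float


def mediate(
    total: MREstimate,
    a: MREstimate,
    b,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
    alpha: float = 0.1,
    second_order: bool = False,
) -> MediationResult:
    """Combine total, exposure->mediator (a) and adjusted mediator->outcome
    (b) estimates into a mediation decomposition.

    ``b`` may be any object with ``beta`` and ``se`` attributes (typically an
    :class:`~mrpipe.mvmr.MVMRRecord`).  When the total effect is zero the
    mediated proportion is undefined and reported as NaN.
    """
    indirect = a.beta * b.beta
    var = a.beta**2 * b.se**2 + b.beta**2 * a.se**2
    if second_order:
        var += a.se**2 * b.se**2
    se_ind = math.sqrt(var)
    ci_low = indirect - Z95 * se_ind
    ci_high = indirect + Z95 * se_ind
    if se_ind > 0:
        pval = float(min(1.0, 2.0 * stats.norm.sf(abs(indirect / se_ind))))
    else:
        pval = 1.0 if indirect == 0 else 0.0
    direct = total.beta - indirect
    if total.beta != 0:
        proportion = indirect / total.beta
    else:
        proportion = math.nan
    se_direct = math.sqrt(total.se**2 + se_ind**2)
    if se_direct > 0:
        p_direct = float(min(1.0, 2.0 * stats.norm.sf(abs(direct / se_direct))))
    else:
        p_direct = 1.0 if direct == 0 else 0.0

    ind_sig = pval < alpha
    dir_sig = p_direct < alpha
    if not ind_sig:
        classification = "none"
    elif total.beta != 0 and math.copysign(1, indirect) != math.copysign(1, total.beta):
        classification = "inconsistent"
    elif dir_sig:
        classification = "partial"
    else:
        classification = "complete"

    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        total=total.beta,
        se_total=total.se,
        beta_a=a.beta,
        se_a=a.se,
        beta_b=b.beta,
        se_b=b.se,
        indirect=indirect,
        se_indirect=se_ind,
        ci_low=ci_low,
        ci_high=ci_high,
        direct=direct,
        proportion=proportion,
        proportion_abs=abs(proportion) if not math.isnan(proportion) else math.nan,
        pval=pval,
        classification=classification,
        alpha=alpha,
    )


def mediation_scan(
    microbe_panels: Sequence[GwasPanel],
    mediator_panels: Sequence[GwasPanel],
    outcome: GwasPanel,
    ld: LDMatrix,
    params: SelectionParams,
    *,
    alpha_mediation: float = 0.1,
    gate_alpha: float = 0.05,
    run_presso: bool = True,
    presso_n_sim: int = 2000,
    presso_seed: int = 0,
    palindrome_eaf_window: float = 0.08,
) -> tuple[list[MediationResult], list[dict]]:
    """Screen every (exposure, mediator) pair against one outcome.

    Per exposure: total effect = univariable IVW on its fully selected
    instruments.  Per pair: beta_a = univariable IVW of the exposure's
    (exposure-side-selected) instruments on the mediator panel, gated at
    ``gate_alpha``; beta_b = the mediator coefficient from pairwise MVMR of
    exposure + mediator on the outcome.  Failing pairs are recorded, never
    fatal.
    """
    results: list[MediationResult] = []
    failures: list[dict] = []

    def fail(exp_id, med_id, stage, exc):
        failures.append(
            {
                "exposure_id": exp_id,
                "mediator_id": med_id,
                "stage": stage,
                "error": type(exc).__name__ if isinstance(exc, Exception) else "gate",
                "message": str(exc),
            }
        )

    for microbe in microbe_panels:
        try:
            iset = select_instruments(
                microbe,
                outcome,
                ld,
                params,
                run_presso=run_presso,
                presso_n_sim=presso_n_sim,
                presso_seed=presso_seed,
                palindrome_eaf_window=palindrome_eaf_window,
            )
            total = ivw(iset.harmonised)
            base_panel, _ = exposure_side_instruments(microbe, ld, params)
        except MRPipeError as exc:
            for med in mediator_panels:
                fail(microbe.trait_id, med.trait_id, "exposure_selection", exc)
            continue
        for med in mediator_panels:
            try:
                hset_a = harmonise(base_panel, med, palindrome_eaf_window)
                a = ivw(hset_a)
            except (EmptyOverlapError, NoInstrumentError) as exc:
                fail(microbe.trait_id, med.trait_id, "a_estimate", exc)
                continue
            if a.pval >= gate_alpha:
                fail(
                    microbe.trait_id,
                    med.trait_id,
                    "gate",
                    f"exposure->mediator p={a.pval:.3g} >= {gate_alpha}",
                )
                continue
            try:
                med_panel, _ = exposure_side_instruments(med, ld, params)
                inp = build_mvmr_input(
                    {
                        microbe.trait_id: iset.harmonised.snp_ids,
                        med.trait_id: med_panel.snp_ids,
                    },
                    {microbe.trait_id: microbe, med.trait_id: med},
                    outcome,
                    ld=ld,
                    clump_window_kb=params.clump_window_kb,
                    clump_r2=params.clump_r2,
                    palindrome_eaf_window=palindrome_eaf_window,
                )
                est = mvmr_ivw(inp)
                b = est[med.trait_id]
            except MRPipeError as exc:
                fail(microbe.trait_id, med.trait_id, "mvmr", exc)
                continue
            results.append(
                mediate(
                    total,
                    a,
                    b,
                    exposure_id=microbe.trait_id,
                    mediator_id=med.trait_id,
                    outcome_id=outcome.trait_id,
                    alpha=alpha_mediation,
                )
            )
    return results, failures
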