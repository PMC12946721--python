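"""Multivariable IVW: each exposure's effect on the outcome conditional on
the others.  Supplies the mediator-on-outcome effect adjusted for the
exposure in two-step mediation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import IdentificationError, ValidationError
from .iv_selection import clump
from .mr_estimators import Z95, _two_sided_p
from .sumstats_io import GwasPanel, HarmonisedSet, align_alleles
from .synthetic_gwas import LDMatrix


@dataclass(frozen=True)
class MVMRInput:
    """Per-SNP effects on every exposure plus the outcome, jointly oriented."""

    snp_ids: tuple[str, ...]
    beta_X: np.ndarray  # (n_snp, n_exposures)
    se_X: np.ndarray
    beta_Y: np.ndarray
    se_Y: np.ndarray
    exposure_ids: tuple[str, ...]
    dropped: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "beta_X", np.asarray(self.beta_X, float))
        object.__setattr__(self, "se_X", np.asarray(self.se_X, float))
        object.__setattr__(self, "beta_Y", np.asarray(self.beta_Y, float))
        object.__setattr__(self, "se_Y", np.asarray(self.se_Y, float))
        n, k = self.beta_X.shape
        if len(self.snp_ids) != n or self.se_X.shape != (n, k):
            raise ValidationError("inconsistent MVMR dimensions")
        if len(self.exposure_ids) != k:
            raise ValidationError("exposure_ids does not match beta_X columns")
        if len(self.beta_Y) != n or len(self.se_Y) != n:
            raise ValidationError("outcome vectors do not match n_snp")
        if n <= k:
            raise IdentificationError(
                f"{n} SNPs cannot identify {k} exposures (need n_snp > n_exposures)"
            )

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class MVMRRecord:
    exposure_id: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_low: float
    or_high: float


@dataclass(frozen=True)
class MVMREstimate:
    exposure_ids: tuple[str, ...]
    records: dict
    q_resid: float
    q_df: int
    n_snp: int
    notes: tuple[str, ...] = ()

    def __getitem__(self, exposure_id: str) -> MVMRRecord:
        return self.records[exposure_id]


def build_mvmr_input(
    instruments: Mapping[str, Iterable[str] | HarmonisedSet],
    exposure_panels: Mapping[str, GwasPanel],
    outcome: GwasPanel,
    ld: LDMatrix | None = None,
    clump_window_kb: int = 500,
    clump_r2: float = 0.01,
    palindrome_eaf_window: float = 0.08,
) -> MVMRInput:
    """Assemble the joint design from each exposure's selected instruments.

    The SNP set is the union of the per-exposure instruments, jointly
    re-clumped when an LD matrix is supplied (lead p-value = the smallest
    p across exposures carrying the SNP).  Every SNP is oriented to the
    effect allele of the first exposure panel that contains it; SNPs missing
    from any panel, or with irreconcilable alleles, are dropped and audited.
    """
    if len(instruments) < 2:
        raise ValidationError("MVMR needs at least two exposures")
    exposure_ids = tuple(instruments.keys())
    union: list[str] = []
    seen: set[str] = set()
    for eid in exposure_ids:
        inst = instruments[eid]
        ids = inst.snp_ids if isinstance(inst, HarmonisedSet) else tuple(inst)
        for s in ids:
            if s not in seen:
                seen.add(s)
                union.append(s)

    dropped: list[tuple[str, str]] = []

    # reference record per SNP: first exposure panel carrying it
    refs: dict[str, tuple[str, object]] = {}
    for s in union:
        for eid in exposure_ids:
            r = exposure_panels[eid].get(s)
            if r is not None:
                refs[s] = (eid, r)
                break
        else:
            dropped.append((s, "missing_in_all_exposures"))
    union = [s for s in union if s in refs]

    if ld is not None and union:
        ref_panel = GwasPanel(
            trait_id="mvmr_union",
            trait_type="continuous",
            records=tuple(
                min(
                    (exposure_panels[eid].get(s) for eid in exposure_ids
                     if exposure_panels[eid].get(s) is not None),
                    key=lambda r: r.pval,
                )
                for s in union
            ),
            sample_size=max(p.sample_size for p in exposure_panels.values()),
        )
        clumped = clump(ref_panel, ld, clump_window_kb, clump_r2)
        kept = set(clumped.snp_ids)
        dropped += [(s, "joint_clump") for s in union if s not in kept]
        union = [s for s in union if s in kept]

    snp_ids: list[str] = []
    rows_bx: list[list[float]] = []
    rows_sx: list[list[float]] = []
    by: list[float] = []
    sy: list[float] = []
    for s in union:
        _, ref = refs[s]
        row_b: list[float] = []
        row_s: list[float] = []
        ok = True
        for eid in exposure_ids:
            r = exposure_panels[eid].get(s)
            if r is None:
                dropped.append((s, f"missing_in_{eid}"))
                ok = False
                break
            sign, reason = align_alleles(
                ref.effect_allele, ref.other_allele, ref.eaf,
                r.effect_allele, r.other_allele, r.eaf,
                palindrome_eaf_window,
            )
            if reason is not None:
                dropped.append((s, f"{reason}_in_{eid}"))
                ok = False
                break
            row_b.append(sign * r.beta)
            row_s.append(r.se)
        if not ok:
            continue
        o = outcome.get(s)
        if o is None:
            dropped.append((s, "missing_in_outcome"))
            continue
        sign, reason = align_alleles(
            ref.effect_allele, ref.other_allele, ref.eaf,
            o.effect_allele, o.other_allele, o.eaf,
            palindrome_eaf_window,
        )
        if reason is not None:
            dropped.append((s, f"{reason}_in_outcome"))
            continue
        snp_ids.append(s)
        rows_bx.append(row_b)
        rows_sx.append(row_s)
        by.append(sign * o.beta)
        sy.append(o.se)

    if len(snp_ids) <= len(exposure_ids):
        raise IdentificationError(
            f"only {len(snp_ids)} usable SNPs for {len(exposure_ids)} exposures"
        )
    return MVMRInput(
        snp_ids=tuple(snp_ids),
        beta_X=np.array(rows_bx),
        se_X=np.array(rows_sx),
        beta_Y=np.array(by),
        se_Y=np.array(sy),
        exposure_ids=exposure_ids,
        dropped=tuple(dropped),
    )


def mvmr_ivw(inp: MVMRInput) -> MVMREstimate:
    """Weighted least squares of outcome betas on the exposure-beta matrix,
    no intercept, weights ``se_Y**-2``.

    SEs use the weighted normal-equations covariance scaled by
    ``max(1, sqrt(Q_resid/(n_snp - n_exposures)))``.
    """
    X, y = inp.beta_X, inp.beta_Y
    n, k = X.shape
    w = 1.0 / inp.se_Y**2
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < k:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{inp.exposure_ids[i]}~{inp.exposure_ids[j]}"
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1.0 - 1e-10
        ]
        raise IdentificationError(
            "rank-deficient exposure matrix"
            + (f"; collinear: {', '.join(pairs)}" if pairs else "")
        )
    notes = []
    if n < 3 * k:
        msg = f"only {n} SNPs for {k} exposures; conditional estimates may be weak"
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    A = X.T @ (X * w[:, None])
    coef = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    dof = n - k
    phi = max(1.0, q / dof)
    cov = np.linalg.inv(A) * phi
    ses = np.sqrt(np.diag(cov))
    records = {}
    for eid, b, s in zip(inp.exposure_ids, coef, ses):
        lo, hi = b - Z95 * s, b + Z95 * s
        records[eid] = MVMRRecord(
            exposure_id=eid,
            beta=float(b),
            se=float(s),
            ci_low=float(lo),
            ci_high=float(hi),
            pval=_two_sided_p(b / s) if s > 0 else (1.0 if b == 0 else 0.0),
            or_=math.exp(b),
            or_low=math.exp(lo),
            or_high=math.exp(hi),
        )
    return MVMREstimate(
        exposure_ids=inp.exposure_ids,
        records=records,
        q_resid=q,
        q_df=dof,
        n_snp=n,
        notes=tuple(notes),
    )
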