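"""Synthetic GWAS summary-statistics generator with known causal structure.

Generates exposure / mediator / binary-outcome panel triplets on one
chromosome, a block-constant LD matrix, and the generative ground truth, so
that every downstream stage (harmonisation, clumping, estimation, mediation)
can be verified against known parameters.

Generative model, per SNP j:

* ``eaf_j ~ Uniform(eaf_range)``
* true exposure effect ``gamma_j ~ Normal(0, exposure_effect_sd^2)``
* true mediator effect ``alpha * gamma_j + delta_j`` where
  ``delta_j ~ Normal(0, med_effect_sd^2)`` is a mediator-specific genetic
  component (0 when ``med_effect_sd`` is 0).  Without it the mediator's
  true effects are exactly proportional to the exposure's and the
  mediator's adjusted effect is unidentifiable in multivariable IVW.
* pleiotropy offset ``u_j ~ Normal(mu_p, pleio_sd^2)`` for a ``pleio_frac``
  subset (``mu_p = pleio_sd`` when directional, else 0), 0 otherwise
* true outcome effect
  ``(theta_direct + alpha * b_med) * gamma_j + b_med * delta_j + u_j``
  (log-odds scale)
* observed beta = true effect + Normal noise with
  ``SE = 1 / sqrt(2 * eaf * (1 - eaf) * n_trait)`` per trait;
  p-value = two-sided normal tail of beta/SE.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .sumstats_io import GwasPanel, VariantAssociation, complement, write_sumstats

# non-palindromic (effect, other) pairs only, so label-based harmonisation is
# always unambiguous and allele noise is exactly reversible
_ALLELE_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)

_SNP_SPACING = 50_000  # bp between adjacent SNPs on the synthetic chromosome


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one exposure/mediator/outcome triplet."""

    n_snps: int = 30
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    theta_direct: float = 0.0
    alpha: float = 0.0
    b_med: float = 0.0
    pleio_frac: float = 0.0
    pleio_sd: float = 0.0
    pleio_directional: bool = False
    eaf_range: tuple[float, float] = (0.1, 0.9)
    exposure_effect_sd: float = 0.05
    med_effect_sd: float = 0.0
    ld_block_size: int = 1
    ld_r2: float = 0.0
    allele_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError(f"eaf_range {self.eaf_range} is not a sub-interval of (0,1)")
        for name in ("pleio_frac", "ld_r2", "allele_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("n_snps", "n_exp", "n_med", "n_out", "ld_block_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.exposure_effect_sd <= 0:
            raise ConfigError("exposure_effect_sd must be positive")
        if self.med_effect_sd < 0:
            raise ConfigError("med_effect_sd must be non-negative")
        if self.pleio_sd < 0:
            raise ConfigError("pleio_sd must be non-negative")

    @property
    def theta_total(self) -> float:
        """True total exposure-on-outcome effect: direct + mediated."""
        return self.theta_direct + self.alpha * self.b_med


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise r-squared between SNPs; symmetric, unit diagonal."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        k = len(self.snp_ids)
        if r2.shape != (k, k):
            raise ValidationError(f"r2 shape {r2.shape} does not match {k} SNPs")
        if not np.allclose(r2, r2.T):
            raise ValidationError("r2 matrix is not symmetric")
        if not np.all(np.diag(r2) == 1.0):
            raise ValidationError("r2 diagonal must be exactly 1")
        if np.any(r2 < 0) or np.any(r2 > 1):
            raise ValidationError("r2 entries must lie in [0, 1]")
        object.__setattr__(self, "_idx", {s: i for i, s in enumerate(self.snp_ids)})

    def has(self, snp_id: str) -> bool:
        return snp_id in self._idx

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._idx[a], self._idx[b]])


@dataclass(frozen=True)
class SimTriplet:
    exposure: GwasPanel
    mediator: GwasPanel
    outcome: GwasPanel
    ld: LDMatrix
    truth: dict


@dataclass(frozen=True)
class PanelSet:
    exposures: tuple[GwasPanel, ...]
    outcome: GwasPanel | None
    ld: LDMatrix
    truths: tuple[dict, ...]


def _block_ld(snp_ids: Sequence[str], block_size: int, r2: float) -> LDMatrix:
    k = len(snp_ids)
    m = np.zeros((k, k))
    for start in range(0, k, block_size):
        stop = min(start + block_size, k)
        m[start:stop, start:stop] = r2
    np.fill_diagonal(m, 1.0)
    return LDMatrix(snp_ids=tuple(snp_ids), r2=m)


def _observe(rng, true_beta, eaf, n):
    """Observed (beta, se, pval) for one trait given true per-SNP effects."""
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
    beta = true_beta + rng.normal(0.0, se)
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), 5e-324)
    return beta, se, pval


def simulate_triplet(
    config: SimulationConfig,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
    snp_prefix: str = "rs",
    chrom: str = "1",
) -> SimTriplet:
    """Simulate one exposure / mediator / outcome summary-statistics triplet.

    Deterministic given ``config`` (including its seed).  A fraction
    ``config.allele_noise`` of outcome rows is emitted with swapped or
    strand-complemented allele labels (beta sign and eaf adjusted to stay
    consistent) to exercise harmonisation.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snps
    snp_ids = [f"{snp_prefix}{j:05d}" for j in range(k)]
    pos = 1 + _SNP_SPACING * np.arange(k)
    eaf = rng.uniform(config.eaf_range[0], config.eaf_range[1], k)
    gamma = rng.normal(0.0, config.exposure_effect_sd, k)
    delta = (
        rng.normal(0.0, config.med_effect_sd, k)
        if config.med_effect_sd > 0
        else np.zeros(k)
    )
    pleio_mask = rng.random(k) < config.pleio_frac
    mu_p = config.pleio_sd if config.pleio_directional else 0.0
    u = np.where(pleio_mask, rng.normal(mu_p, config.pleio_sd, k), 0.0)
    alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), k)]

    true_exp = gamma
    true_med = config.alpha * gamma + delta
    true_out = config.theta_total * gamma + config.b_med * delta + u

    b_exp, se_exp, p_exp = _observe(rng, true_exp, eaf, config.n_exp)
    b_med, se_med, p_med = _observe(rng, true_med, eaf, config.n_med)
    b_out, se_out, p_out = _observe(rng, true_out, eaf, config.n_out)

    noise_mask = rng.random(k) < config.allele_noise
    noise_mode = rng.integers(0, 3, k)  # 0 swap, 1 complement, 2 complement+swap

    def rec(i, trait_n, beta, se, pval, noised=False):
        ea, oa = alleles[i]
        b, f = beta[i], eaf[i]
        if noised and noise_mask[i]:
            if noise_mode[i] in (1, 2):
                ea, oa = complement(ea), complement(oa)
            if noise_mode[i] in (0, 2):
                ea, oa = oa, ea
                b, f = -b, 1.0 - f
        return VariantAssociation(
            snp_id=snp_ids[i],
            chrom=chrom,
            pos=int(pos[i]),
            effect_allele=ea,
            other_allele=oa,
            eaf=float(f),
            beta=float(b),
            se=float(se[i]),
            pval=float(pval[i]),
            n=trait_n,
        )

    exposure = GwasPanel(
        trait_id=exposure_id,
        trait_type="continuous",
        records=tuple(rec(i, config.n_exp, b_exp, se_exp, p_exp) for i in range(k)),
        sample_size=config.n_exp,
    )
    mediator = GwasPanel(
        trait_id=mediator_id,
        trait_type="continuous",
        records=tuple(rec(i, config.n_med, b_med, se_med, p_med) for i in range(k)),
        sample_size=config.n_med,
    )
    outcome = GwasPanel(
        trait_id=outcome_id,
        trait_type="binary",
        records=tuple(
            rec(i, config.n_out, b_out, se_out, p_out, noised=True) for i in range(k)
        ),
        sample_size=config.n_out,
    )
    ld = _block_ld(snp_ids, config.ld_block_size, config.ld_r2)
    truth = {
        "seed": config.seed,
        "gamma": gamma.tolist(),
        "delta": delta.tolist(),
        "u": u.tolist(),
        "pleio_mask": pleio_mask.tolist(),
        "allele_noise_mask": noise_mask.tolist(),
        "eaf": eaf.tolist(),
        "theta_direct": config.theta_direct,
        "alpha": config.alpha,
        "b_med": config.b_med,
        "theta_total": config.theta_total,
        "config": asdict(config),
    }
    return SimTriplet(exposure=exposure, mediator=mediator, outcome=outcome, ld=ld, truth=truth)


def simulate_panel_set(
    configs: Sequence[SimulationConfig],
    shared_outcome: bool = True,
    trait_ids: Sequence[str] | None = None,
    outcome_id: str = "outcome",
) -> PanelSet:
    """One exposure panel per config, optionally with a single shared outcome.

    Each config contributes its own (disjointly named) SNPs; the shared
    outcome panel is their concatenation, so each exposure's instruments find
    their outcome effects in it.  The combined LD matrix is block-diagonal
    across configs.
    """
    if not configs:
        raise ConfigError("simulate_panel_set needs at least one config")
    if trait_ids is None:
        trait_ids = [f"trait_{i:03d}" for i in range(len(configs))]
    if len(trait_ids) != len(configs):
        raise ConfigError("trait_ids and configs length mismatch")
    if len(set(trait_ids)) != len(trait_ids):
        raise ConfigError(f"duplicate trait ids: {trait_ids}")

    exposures: list[GwasPanel] = []
    truths: list[dict] = []
    out_records: list[VariantAssociation] = []
    ld_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for i, (cfg, tid) in enumerate(zip(configs, trait_ids)):
        trip = simulate_triplet(
            cfg,
            exposure_id=tid,
            mediator_id=f"{tid}_mediator",
            outcome_id=outcome_id,
            snp_prefix=f"t{i}_rs",
            chrom=str(i + 1),  # one synthetic chromosome per trait
        )
        exposures.append(trip.exposure)
        truths.append(trip.truth)
        out_records.extend(trip.outcome.records)
        ld_ids.extend(trip.ld.snp_ids)
        blocks.append(trip.ld.r2)
    outcome = None
    if shared_outcome:
        n_out = max(cfg.n_out for cfg in configs)
        outcome = GwasPanel(
            trait_id=outcome_id,
            trait_type="binary",
            records=tuple(out_records),
            sample_size=n_out,
        )
    k = len(ld_ids)
    m = np.zeros((k, k))
    start = 0
    for b in blocks:
        stop = start + b.shape[0]
        m[start:stop, start:stop] = b
        start = stop
    ld = LDMatrix(snp_ids=tuple(ld_ids), r2=m)
    return PanelSet(exposures=tuple(exposures), outcome=outcome, ld=ld, truths=tuple(truths))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> Path:
    """LD matrix as TSV: header row of snp ids, then one labelled row each."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("snp_id\t" + "\t".join(ld.snp_ids) + "\n")
        for i, s in enumerate(ld.snp_ids):
            fh.write(s + "\t" + "\t".join(f"{v:.17g}" for v in ld.r2[i]) + "\n")
    return path


def read_ld_matrix(path: str | Path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(snp_ids=tuple(str(c) for c in df.columns), r2=df.to_numpy(dtype=float))


def write_triplet(triplet: SimTriplet, out_dir: str | Path) -> Path:
    """Write a triplet's panels, LD matrix and ground truth under one directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for panel in (triplet.exposure, triplet.mediator, triplet.outcome):
        write_sumstats(panel, out_dir / f"{panel.trait_id}.tsv")
    write_ld_matrix(triplet.ld, out_dir / "ld.tsv")
    (out_dir / "truth.json").write_text(json.dumps(triplet.truth, indent=2))
    return out_dir
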