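"""Reading, writing, validation and harmonisation of GWAS summary statistics.

The on-disk dialect is a 10-column tab-separated table with a header row::

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

UTF-8, '.' decimal separator, no thousands separators.  ``eaf`` may be ``NA``
(missing); palindromic SNPs with a missing frequency can never be
disambiguated and are dropped at harmonisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError, FormatError, ValidationError

CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

TRAIT_TYPES = ("continuous", "binary")

#: Closed vocabulary for per-SNP harmonisation drops.
DROP_REASONS = ("missing_in_outcome", "palindromic_ambiguous", "allele_mismatch")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Strand complement of a single-nucleotide allele."""
    return _COMPLEMENT[allele]


def is_palindromic(a: str, b: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be inferred."""
    return _COMPLEMENT.get(a) == b


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary-level association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``; for binary traits
    it is on the log-odds scale.  ``eaf`` may be NaN when unknown.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self):
        problems = _record_problems(self.__dict__)
        if problems:
            raise ValidationError(f"record {self.snp_id!r}: " + "; ".join(problems))


def _record_problems(row: Mapping) -> list[str]:
    """Invariant check on one record's raw field values; returns messages."""
    problems: list[str] = []
    ea = str(row["effect_allele"]).upper()
    oa = str(row["other_allele"]).upper()
    if ea not in _COMPLEMENT:
        problems.append(f"effect_allele {ea!r} not in A/C/G/T")
    if oa not in _COMPLEMENT:
        problems.append(f"other_allele {oa!r} not in A/C/G/T")
    if ea == oa:
        problems.append("effect_allele equals other_allele")
    try:
        pos = int(row["pos"])
        if pos < 0:
            problems.append("pos is negative")
    except (TypeError, ValueError):
        problems.append(f"pos {row['pos']!r} not an integer")
    eaf = float(row["eaf"])
    if not math.isnan(eaf) and not 0.0 < eaf < 1.0:
        problems.append(f"eaf {eaf} outside (0, 1)")
    se = float(row["se"])
    if not se > 0.0:
        problems.append(f"se {se} not positive")
    pval = float(row["pval"])
    if not 0.0 < pval <= 1.0:
        problems.append(f"pval {pval} outside (0, 1]")
    try:
        n = int(row["n"])
        if n <= 0:
            problems.append("n not positive")
    except (TypeError, ValueError):
        problems.append(f"n {row['n']!r} not an integer")
    return problems


@dataclass(frozen=True)
class GwasPanel:
    """All summary records for one GWAS trait, in file order."""

    trait_id: str
    trait_type: str
    records: tuple[VariantAssociation, ...]
    sample_size: int
    diagnostics: tuple[str, ...] = ()

    def __post_init__(self):
        if self.trait_type not in TRAIT_TYPES:
            raise ValidationError(
                f"trait_type {self.trait_type!r} not one of {TRAIT_TYPES}"
            )
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError(f"panel {self.trait_id!r} is empty")
        if self.sample_size <= 0:
            raise ValidationError("sample_size must be positive")
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValidationError(
                f"duplicate snp_id in panel {self.trait_id!r}: {sorted(dups)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(r.snp_id for r in self.records)

    def get(self, snp_id: str) -> VariantAssociation | None:
        return self._index().get(snp_id)

    def _index(self) -> dict[str, VariantAssociation]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {r.snp_id: r for r in self.records}
            object.__setattr__(self, "_idx", idx)
        return idx

    def subset(self, snp_ids: Iterable[str]) -> "GwasPanel":
        """Sub-panel with the given SNPs, preserving this panel's order."""
        wanted = set(snp_ids)
        kept = tuple(r for r in self.records if r.snp_id in wanted)
        return replace(self, records=kept, diagnostics=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=CANONICAL_COLUMNS)


def read_sumstats(
    path: str | Path,
    trait_id: str,
    trait_type: str = "continuous",
    sample_size: int | None = None,
    strict: bool = True,
) -> GwasPanel:
    """Read one trait's summary statistics from a tab-separated file.

    Rows violating record invariants raise :class:`ValidationError` naming the
    offending 1-based data rows when ``strict``; otherwise they are skipped and
    reported in ``panel.diagnostics``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str, "chrom": str},
        float_precision="round_trip",
    )
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[VariantAssociation] = []
    diagnostics: list[str] = []
    for i, row in enumerate(df[list(CANONICAL_COLUMNS)].itertuples(index=False), start=1):
        raw = dict(zip(CANONICAL_COLUMNS, row))
        problems = _record_problems(raw)
        if problems:
            diagnostics.append(f"row {i} ({raw['snp_id']}): " + "; ".join(problems))
            continue
        records.append(
            VariantAssociation(
                snp_id=str(raw["snp_id"]),
                chrom=str(raw["chrom"]),
                pos=int(raw["pos"]),
                effect_allele=str(raw["effect_allele"]).upper(),
                other_allele=str(raw["other_allele"]).upper(),
                eaf=float(raw["eaf"]),
                beta=float(raw["beta"]),
                se=float(raw["se"]),
                pval=float(raw["pval"]),
                n=int(raw["n"]),
            )
        )
    if strict and diagnostics:
        raise ValidationError(f"{path}: invalid rows -- " + " | ".join(diagnostics))
    if not records:
        raise ValidationError(f"{path}: no valid records")
    if sample_size is None:
        sample_size = max(r.n for r in records)
    return GwasPanel(
        trait_id=trait_id,
        trait_type=trait_type,
        records=tuple(records),
        sample_size=sample_size,
        diagnostics=tuple(diagnostics),
    )


def write_sumstats(panel: GwasPanel, path: str | Path) -> Path:
    """Write a panel in the canonical column order, round-trip safe.

    Floats are written with 17 significant digits so that
    ``read_sumstats(write_sumstats(p))`` reproduces every value bit-exactly.
    """
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for r in panel.records:
        eaf = "NA" if math.isnan(r.eaf) else f"{r.eaf:.17g}"
        lines.append(
            "\t".join(
                [
                    r.snp_id,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    eaf,
                    f"{r.beta:.17g}",
                    f"{r.se:.17g}",
                    f"{r.pval:.17g}",
                    str(r.n),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@dataclass(frozen=True)
class HarmonisedSet:
    """Exposure/outcome effects aligned to the exposure's effect allele.

    ``eaf`` is the exposure-panel effect-allele frequency.  ``dropped`` lists
    (snp_id, reason) pairs for shared-but-unusable SNPs, with reasons drawn
    from :data:`DROP_REASONS`.
    """

    snp_ids: tuple[str, ...]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf: np.ndarray
    n_exp: np.ndarray
    n_out: np.ndarray
    dropped: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "eaf"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("n_exp", "n_out"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        object.__setattr__(self, "dropped", tuple((s, r) for s, r in self.dropped))
        k = len(self.snp_ids)
        if k < 1:
            raise ValidationError("HarmonisedSet must retain at least one SNP")
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "eaf", "n_exp", "n_out"):
            if len(getattr(self, name)) != k:
                raise ValidationError(f"length mismatch in {name}")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValidationError("standard errors must be positive")
        for _, reason in self.dropped:
            if reason not in DROP_REASONS:
                raise ValidationError(f"unknown drop reason {reason!r}")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, snp_ids: Iterable[str]) -> "HarmonisedSet":
        wanted = set(snp_ids)
        idx = [i for i, s in enumerate(self.snp_ids) if s in wanted]
        if not idx:
            raise ValidationError("subset would be empty")
        return HarmonisedSet(
            snp_ids=tuple(self.snp_ids[i] for i in idx),
            beta_exp=self.beta_exp[idx],
            se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx],
            se_out=self.se_out[idx],
            eaf=self.eaf[idx],
            n_exp=self.n_exp[idx],
            n_out=self.n_out[idx],
            dropped=self.dropped,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta_exp": self.beta_exp,
                "se_exp": self.se_exp,
                "beta_out": self.beta_out,
                "se_out": self.se_out,
                "eaf": self.eaf,
                "n_exp": self.n_exp,
                "n_out": self.n_out,
            }
        )


def align_alleles(
    ref_effect: str,
    ref_other: str,
    ref_eaf: float,
    effect: str,
    other: str,
    eaf: float,
    palindrome_eaf_window: float = 0.08,
) -> tuple[int, str | None]:
    """Orient one record's alleles onto a reference orientation.

    Returns ``(sign, None)`` where ``sign`` multiplies the record's beta
    (+1 as-written / after strand complement, -1 when alleles are swapped),
    or ``(0, reason)`` when the record must be dropped.

    Palindromic pairs (A/T, C/G) cannot be oriented by strand, so after
    label alignment both effect-allele frequencies must fall on the same
    side of 0.5 and outside ``0.5 +/- palindrome_eaf_window``.
    """
    if is_palindromic(ref_effect, ref_other):
        if (effect, other) == (ref_effect, ref_other):
            sign, f = 1, eaf
        elif (effect, other) == (ref_other, ref_effect):
            sign, f = -1, (1.0 - eaf)
        else:
            return 0, "allele_mismatch"
        if math.isnan(ref_eaf) or math.isnan(f):
            return 0, "palindromic_ambiguous"
        if abs(ref_eaf - 0.5) <= palindrome_eaf_window or abs(f - 0.5) <= palindrome_eaf_window:
            return 0, "palindromic_ambiguous"
        if (ref_eaf - 0.5) * (f - 0.5) <= 0:
            return 0, "palindromic_ambiguous"
        return sign, None
    for strand_flip in (False, True):
        a, b = (complement(effect), complement(other)) if strand_flip else (effect, other)
        if (a, b) == (ref_effect, ref_other):
            return 1, None
        if (a, b) == (ref_other, ref_effect):
            return -1, None
    return 0, "allele_mismatch"


def harmonise(
    exposure: GwasPanel,
    outcome: GwasPanel,
    palindrome_eaf_window: float = 0.08,
) -> HarmonisedSet:
    """Align outcome effects to the exposure's effect-allele orientation.

    The exposure effect allele is the reference.  Swapped outcome alleles get
    their beta sign flipped and eaf complemented; strand complements are
    resolved first; palindromic SNPs are kept only when both frequencies agree
    (see :func:`align_alleles`).  SNPs absent from the outcome panel are
    dropped with reason ``missing_in_outcome``.
    """
    if not 0.0 <= palindrome_eaf_window < 0.5:
        raise ValidationError("palindrome_eaf_window must be in [0, 0.5)")
    shared = 0
    kept: list[VariantAssociation] = []
    signs: list[int] = []
    out_recs: list[VariantAssociation] = []
    dropped: list[tuple[str, str]] = []
    for e in exposure:
        o = outcome.get(e.snp_id)
        if o is None:
            dropped.append((e.snp_id, "missing_in_outcome"))
            continue
        shared += 1
        sign, reason = align_alleles(
            e.effect_allele,
            e.other_allele,
            e.eaf,
            o.effect_allele,
            o.other_allele,
            o.eaf,
            palindrome_eaf_window,
        )
        if reason is not None:
            dropped.append((e.snp_id, reason))
            continue
        kept.append(e)
        signs.append(sign)
        out_recs.append(o)
    if shared == 0:
        raise EmptyOverlapError(
            f"panels {exposure.trait_id!r} and {outcome.trait_id!r} share no SNPs"
        )
    if not kept:
        raise EmptyOverlapError(
            f"all {shared} shared SNPs between {exposure.trait_id!r} and "
            f"{outcome.trait_id!r} were dropped at harmonisation"
        )
    return HarmonisedSet(
        snp_ids=tuple(e.snp_id for e in kept),
        beta_exp=np.array([e.beta for e in kept]),
        se_exp=np.array([e.se for e in kept]),
        beta_out=np.array([s * o.beta for s, o in zip(signs, out_recs)]),
        se_out=np.array([o.se for o in out_recs]),
        eaf=np.array([e.eaf for e in kept]),
        n_exp=np.array([e.n for e in kept]),
        n_out=np.array([o.n for o in out_recs]),
        dropped=tuple(dropped),
    )
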