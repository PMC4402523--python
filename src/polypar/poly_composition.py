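"""Polymorphic-site base composition: VCF ingestion, site filters, HWE tests,
and the per-individual base-composition phenotype.

The phenotype of an individual is the fraction of each base among the SNP
alleles that individual carries: at a biallelic site with reference base R
and alternative base B, a 0/0 homozygote contributes two R alleles, a
heterozygote one R and one B, and a 1/1 homozygote two B alleles (the
ref-allele weights 1 / 0.5 / 0 per site).  frac_X = (# alleles equal to X) /
(2 * number of non-missing sites for that sample), so the four fractions sum
to 1 for every sample.

Coordinates are 0-based half-open internally; VCF's 1-based positions are
converted at the boundary and reported back as 1-based in output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterConfig",
    "GenotypeMatrix",
    "FilterReport",
    "load_variants",
    "read_groups",
    "hwe_test",
    "base_phenotype",
    "mutation_site_composition",
    "allele_freq_divergence",
    "group_separation",
]

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: chromosome names excluded by default (analyses here are autosomal)
SEX_MITO = {"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"}


@dataclass(frozen=True)
class FilterConfig:
    """Site filters, applied in order: biallelic SNP -> (autosome) ->
    call rate -> MAF -> optional HWE.

    MAF is computed on the overall retained sample set, after the call-rate
    filter. HWE removal is off by default (``hwe_alpha=None``): deviation is
    reported per group, not used to drop sites, unless an alpha is given.
    """

    min_call_rate: float = 0.8
    min_maf: float = 0.05
    hwe_alpha: float | None = None
    biallelic_only: bool = True
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_call_rate <= 1.0):
            raise ValueError("min_call_rate must be in [0, 1]")
        if not (0.0 <= self.min_maf <= 1.0):
            raise ValueError("min_maf must be in [0, 1]")
        if self.hwe_alpha is not None and not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError("hwe_alpha must be in (0, 1)")


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of alt-allele dosages in {0,1,2}, -1 missing."""

    samples: list[str]
    dosage: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2 or self.dosage.shape[0] != len(self.samples):
            raise ValueError("dosage shape inconsistent with sample list")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.dosage[:, idx])


@dataclass
class FilterReport:
    """Counts of records removed per rule, in application order."""

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "n_removed": v} for k, v in self.removed.items()]
        rows.append({"rule": "retained", "n_removed": self.n_retained})
        return pd.DataFrame(rows)


def _validate_variant_table(variants: pd.DataFrame) -> None:
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in variants.columns:
            raise ValueError(f"variant table missing column {col!r}")
    bad = ~(variants["ref"].isin(BASES) & variants["alt"].isin(BASES))
    if bad.any():
        raise ValueError("variant table contains non-ACGT ref/alt bases")
    if (variants["ref"] == variants["alt"]).any():
        raise ValueError("variant table contains ref == alt records")
    if variants.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) in variant table")


def load_variants(
    vcf_source: str | Path,
    filters: FilterConfig | None = None,
) -> tuple[pd.DataFrame, GenotypeMatrix, FilterReport]:
    """Read a VCF(.gz), apply site filters, return variants + dosages + report.

    Returns
    -------
    variants : DataFrame with columns chrom, pos (1-based), id, ref, alt.
    genotypes : GenotypeMatrix aligned with the variant rows.
    report : FilterReport itemizing removals per rule.
    """
    from cyvcf2 import VCF

    filters = filters or FilterConfig()
    vcf = VCF(str(vcf_source), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{vcf_source}: VCF has no samples")

    report = FilterReport()
    removed = {
        "not_biallelic_snp": 0,
        "non_autosome": 0,
        "low_call_rate": 0,
        "low_maf": 0,
        "hwe": 0,
    }
    rows: list[tuple] = []
    dosages: list[np.ndarray] = []
    for rec in vcf:
        report.n_input += 1
        if filters.biallelic_only and (
            len(rec.ALT) != 1
            or len(rec.REF) != 1
            or rec.REF not in BASES
            or rec.ALT[0] not in BASES
        ):
            removed["not_biallelic_snp"] += 1
            continue
        if filters.autosomes_only and rec.CHROM in SEX_MITO:
            removed["non_autosome"] += 1
            continue
        # gts012=True: 0/1/2 = alt dosage, 3 = unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        if gt.shape[0] != len(samples):
            raise ValueError(f"malformed GT at {rec.CHROM}:{rec.POS}")
        missing = gt == 3
        gt[missing] = -1
        call_rate = 1.0 - missing.mean()
        if call_rate < filters.min_call_rate or call_rate == 0.0:
            removed["low_call_rate"] += 1
            continue
        n_called = int((~missing).sum())
        p_alt = gt[~missing].sum() / (2 * n_called)
        if min(p_alt, 1.0 - p_alt) < filters.min_maf:
            removed["low_maf"] += 1
            continue
        if filters.hwe_alpha is not None:
            n_aa = int((gt == 0).sum())
            n_ab = int((gt == 1).sum())
            n_bb = int((gt == 2).sum())
            if hwe_test(n_aa, n_ab, n_bb) < filters.hwe_alpha:
                removed["hwe"] += 1
                continue
        rows.append((rec.CHROM, rec.POS, rec.ID or ".", rec.REF, rec.ALT[0]))
        dosages.append(gt)

    report.removed = removed
    report.n_retained = len(rows)
    if not rows:
        raise ValueError(f"{vcf_source}: no variants survive the filters")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    _validate_variant_table(variants)
    genotypes = GenotypeMatrix(samples, np.column_stack(dosages))
    return variants, genotypes, report


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column sample/group TSV into a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str, comment="#")
    return df.set_index("sample")["group"]


def hwe_test(n_aa: int, n_ab: int, n_bb: int, method: str = "chisq") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``method='chisq'``: 1-df chi-square goodness of fit against expected
    counts at the observed allele frequency. ``method='exact'``: exact
    conditional test on the heterozygote count (two-sided by probability
    mass), preferable for small counts. A monomorphic site returns p = 1 by
    convention.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotyped samples")
    n_b = n_ab + 2 * n_bb
    if n_b == 0 or n_b == 2 * n:
        return 1.0
    if method == "chisq":
        p = 1.0 - n_b / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_aa, n_ab, n_bb], dtype=float)
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n_aa, n_ab, n_bb)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test: probability of heterozygote counts no more likely than
    the observed one, conditional on the allele counts (Levene/Haldane
    distribution)."""
    n = n_aa + n_ab + n_bb
    rare = min(n_ab + 2 * n_aa, n_ab + 2 * n_bb)
    parity = rare % 2
    hets = np.arange(parity, rare + 1, 2)
    # log P(n_het = h | rare allele count) up to a constant
    from scipy.special import gammaln

    common = 2 * n - rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln((common - hets) / 2 + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_ab][0]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


def _allele_base_counts(
    variants: pd.DataFrame, genotypes: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample counts of each base among carried alleles, plus the number
    of non-missing sites per sample. Vectorized over one-hot base indicators."""
    dos = genotypes.dosage.astype(np.float64)
    missing = dos < 0
    dos[missing] = 0.0
    nonmiss = (~missing).astype(np.float64)
    ref_onehot = np.zeros((len(variants), 4))
    alt_onehot = np.zeros((len(variants), 4))
    ref_onehot[np.arange(len(variants)), [_BASE_INDEX[b] for b in variants["ref"]]] = 1.0
    alt_onehot[np.arange(len(variants)), [_BASE_INDEX[b] for b in variants["alt"]]] = 1.0
    # alt alleles carried at site j: dosage; ref alleles: 2 - dosage (non-missing only)
    alt_counts = dos @ alt_onehot
    ref_counts = (2.0 * nonmiss - dos) @ ref_onehot
    return alt_counts + ref_counts, nonmiss.sum(axis=1)


def base_phenotype(variants: pd.DataFrame, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual base-composition phenotype across polymorphic sites.

    Returns a DataFrame indexed by sample with columns frac_a, frac_c,
    frac_g, frac_t, n_sites_used. Sites with a missing genotype are excluded
    from that sample's denominator, so the fractions always sum to 1.
    Samples with zero non-missing sites get NaN fractions and are flagged by
    ``n_sites_used == 0``.
    """
    _validate_variant_table(variants)
    if len(variants) != genotypes.n_variants:
        raise ValueError("variant table and genotype matrix disagree on variant count")
    counts, n_sites = _allele_base_counts(variants, genotypes)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = counts / (2.0 * n_sites[:, None])
    out = pd.DataFrame(
        fracs,
        index=pd.Index(genotypes.samples, name="sample"),
        columns=["frac_a", "frac_c", "frac_g", "frac_t"],
    )
    out["n_sites_used"] = n_sites.astype(int)
    return out


def mutation_site_composition(mutations: pd.DataFrame) -> pd.DataFrame:
    """Base composition across mutation sites, per line, derived vs ancestor.

    ``mutations`` has columns line, chrom, pos, ref, alt: one row per new
    mutation on the reference strand. For each line the derived composition
    counts the alt bases at its mutation sites and the ancestor composition
    counts the ref bases at the same sites.

    Returns a DataFrame with one row per (line, role) where role is
    ``derived`` or ``ancestor``, columns frac_a..frac_t and n_sites.
    """
    for col in ("line", "ref", "alt"):
        if col not in mutations.columns:
            raise ValueError(f"mutation table missing column {col!r}")
    if len(mutations) == 0:
        raise ValueError("empty mutation table")
    if (mutations["ref"] == mutations["alt"]).any():
        raise ValueError("mutation table contains ref == alt records")
    rows = []
    for line, sub in mutations.groupby("line", sort=True):
        n = len(sub)
        for role, col in (("derived", "alt"), ("ancestor", "ref")):
            counts = sub[col].value_counts()
            rows.append(
                {
                    "line": line,
                    "role": role,
                    **{f"frac_{b.lower()}": counts.get(b, 0) / n for b in BASES},
                    "n_sites": n,
                }
            )
    return pd.DataFrame(rows)


def allele_freq_divergence(
    genotypes: GenotypeMatrix,
    groups: pd.Series,
    group1: str,
    group2: str,
) -> pd.DataFrame:
    """Per-variant absolute alt-allele frequency difference |p1 - p2|.

    Missing genotypes are excluded per group. Sites where either group has
    no called genotype get NaN and ``defined=False``.
    """
    labels = groups.reindex(genotypes.samples)
    out = {}
    for g in (group1, group2):
        mask = (labels == g).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has no samples in the genotype matrix")
        dos = genotypes.dosage[mask].astype(float)
        miss = dos < 0
        dos[miss] = 0.0
        n_called = (~miss).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[g] = np.where(n_called > 0, dos.sum(axis=0) / (2 * n_called), np.nan)
    div = np.abs(out[group1] - out[group2])
    return pd.DataFrame({"divergence": div, "defined": ~np.isnan(div)})


def group_separation(
    phenotype: pd.DataFrame,
    groups: pd.Series,
    basal: str | None = None,
    derived: str | None = None,
) -> dict:
    """Per-group mean/sd of each base fraction plus a Welch test on frac_a.

    The test direction is reported as derived minus basal. When group roles
    are not given, the two labels present are used with the first (sorted)
    as basal.
    """
    labels = groups.reindex(phenotype.index)
    present = sorted(labels.dropna().unique())
    if len(present) < 2:
        raise ValueError("group_separation requires at least two groups")
    if basal is None or derived is None:
        basal, derived = present[0], present[1]
    frac_cols = ["frac_a", "frac_c", "frac_g", "frac_t"]
    summary = (
        phenotype.assign(group=labels)
        .dropna(subset=["group"])
        .groupby("group")[frac_cols]
        .agg(["mean", "std", "count"])
    )
    a_basal = phenotype.loc[labels == basal, "frac_a"].dropna()
    a_derived = phenotype.loc[labels == derived, "frac_a"].dropna()
    if len(a_basal) < 2 or len(a_derived) < 2:
        raise ValueError("need >= 2 samples per group for the Welch test")
    t, p = stats.ttest_ind(a_derived, a_basal, equal_var=False)
    return {
        "summary": summary,
        "basal": basal,
        "derived": derived,
        "diff_frac_a": float(a_derived.mean() - a_basal.mean()),
        "welch_t": float(t),
        "p_value": float(p),
    }


def write_phenotype(
    phenotype: pd.DataFrame, path: str | Path, groups: pd.Series | None = None
) -> None:
    out = phenotype.copy()
    if groups is not None:
        out.insert(0, "group", groups.reindex(out.index))
    out.to_csv(path, sep="\t")


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return df
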