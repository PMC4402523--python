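"""Synthetic inputs with the statistical structure the analyses assume.

Three generators:

* a strand-symmetric (no-strand-bias) mutation spectrum with a tunable bias
  toward A:T, plus single-mutation draws that model the strand on which the
  mutation arises;
* a two-group (basal / derived-through-a-bottleneck) population of biallelic
  SNPs with HWE genotypes within groups, group-private variants, and an
  optional causal "bias-modifier" locus whose carriers accrue extra variants
  with an amplified AT bias;
* mutation-accumulation lines propagated from a common ancestor sequence.

The no-strand-bias hypothesis: if mutations arise on either strand with
equal probability and each rate equals the rate of its complementary
substitution, tallies on one strand satisfy PR2 in expectation.  The
spectrum type enforces the 6 complementary-pair equalities exactly.

Every generator consumes a single integer seed; all outputs regenerate
bit-identically from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .poly_composition import GenotypeMatrix

__all__ = [
    "MutationSpectrum",
    "Bottleneck",
    "ModifierConfig",
    "PopSimConfig",
    "MutAccumConfig",
    "PopSim",
    "MutAccumSim",
    "draw_mutation",
    "random_sequence",
    "simulate_populations",
    "simulate_mut_accum",
    "simulate_gene_annotation",
    "write_vcf",
]

BASES = ("A", "C", "G", "T")
_IDX = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: index of the complementary base, aligned with BASES order
_COMP_IDX = np.array([3, 2, 1, 0])


class MutationSpectrum:
    """12 substitution rates r(X->Y) constrained strand-symmetric.

    Strand symmetry means r(X->Y) == r(comp(X)->comp(Y)) for every pair, so
    only 6 rates are free; they are given for the substitutions out of A and
    C and mirrored onto T and G.
    """

    def __init__(self, rates: dict[tuple[str, str], float]):
        R = np.zeros((4, 4))
        for (x, y), r in rates.items():
            if x == y:
                raise ValueError("spectrum keys must have distinct bases")
            if r < 0:
                raise ValueError("substitution rates must be non-negative")
            R[_IDX[x], _IDX[y]] = r
        # mirror the free half onto complements; verify consistency if both given
        for x in "AC":
            for y in BASES:
                if y == x:
                    continue
                cx, cy = _COMP[x], _COMP[y]
                given = R[_IDX[cx], _IDX[cy]]
                if given and not np.isclose(given, R[_IDX[x], _IDX[y]]):
                    raise ValueError(
                        f"rates violate strand symmetry: r({x}->{y}) != r({cx}->{cy})"
                    )
                R[_IDX[cx], _IDX[cy]] = R[_IDX[x], _IDX[y]]
        if not R.any():
            raise ValueError("spectrum has no positive rates")
        self.rate_matrix = R

    @classmethod
    def uniform(cls) -> "MutationSpectrum":
        return cls.with_at_bias(1.0)

    @classmethod
    def with_at_bias(cls, bias: float) -> "MutationSpectrum":
        """Baseline-1 rates with every substitution *into* A or T scaled by
        ``bias``; bias 1 is the uniform (unbiased) spectrum."""
        if bias <= 0:
            raise ValueError("at bias must be positive")
        rates = {}
        for x in "AC":
            for y in BASES:
                if y != x:
                    rates[(x, y)] = bias if y in "AT" else 1.0
        return cls(rates)

    def scaled_at_bias(self, factor: float) -> "MutationSpectrum":
        """A new spectrum with rates into {A,T} multiplied by ``factor``."""
        R = self.rate_matrix.copy()
        R[:, [_IDX["A"], _IDX["T"]]] *= factor
        np.fill_diagonal(R, 0.0)
        return MutationSpectrum(
            {(x, y): R[_IDX[x], _IDX[y]] for x in "AC" for y in BASES if y != x}
        )

    def at_bias(self, composition: Sequence[float] | None = None) -> float:
        """Total mutational flow into {A,T} over flow into {G,C} from a given
        base composition (default uniform)."""
        pi = np.full(4, 0.25) if composition is None else np.asarray(composition, float)
        flow = pi @ self.rate_matrix
        return float((flow[_IDX["A"]] + flow[_IDX["T"]]) / (flow[_IDX["C"]] + flow[_IDX["G"]]))

    def stationary_composition(self) -> np.ndarray:
        """Stationary base composition of the substitution process (satisfies
        pi_A == pi_T and pi_C == pi_G by strand symmetry)."""
        Q = self.rate_matrix.copy()
        np.fill_diagonal(Q, -Q.sum(axis=1))
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = np.abs(pi)
        return pi / pi.sum()

    def transition_probs(self, ref: str) -> np.ndarray:
        row = self.rate_matrix[_IDX[ref]]
        total = row.sum()
        if total == 0:
            raise ValueError(f"all outgoing rates from {ref!r} are zero")
        return row / total


def draw_mutation(
    ref_base: str, spectrum: MutationSpectrum, rng: np.random.Generator
) -> tuple[str, str]:
    """Draw one substitution at a site with reference-strand base ``ref_base``.

    A strand is chosen uniformly; the substitution is drawn on that strand
    from the spectrum and reported as the equivalent change on the reference
    strand. Returns (alt_base_on_reference_strand, strand) with strand in
    {'+', '-'}. Under a strand-symmetric spectrum the alt distribution is
    the same for both strands; the mechanism is kept explicit because it is
    the generative content of the no-strand-bias hypothesis.
    """
    if ref_base not in _IDX:
        raise ValueError(f"invalid reference base {ref_base!r}")
    strand = "+" if rng.random() < 0.5 else "-"
    template = ref_base if strand == "+" else _COMP[ref_base]
    probs = spectrum.transition_probs(template)
    alt_on_template = BASES[rng.choice(4, p=probs)]
    alt = alt_on_template if strand == "+" else _COMP[alt_on_template]
    return alt, strand


def _draw_alts(
    ref_idx: np.ndarray, spectrum: MutationSpectrum, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw_mutation over an array of reference-base indices."""
    strand_minus = rng.random(ref_idx.shape[0]) < 0.5
    template = np.where(strand_minus, _COMP_IDX[ref_idx], ref_idx)
    u = rng.random(ref_idx.shape[0])
    R = spectrum.rate_matrix
    rowsum = R.sum(axis=1)
    if np.any(rowsum[np.unique(template)] == 0):
        bad = BASES[int(np.unique(template)[rowsum[np.unique(template)] == 0][0])]
        raise ValueError(f"all outgoing rates from {bad!r} are zero")
    cum = np.cumsum(R, axis=1) / np.where(rowsum, rowsum, 1.0)[:, None]
    alt_t = (u[:, None] > cum[template]).sum(axis=1)
    return np.where(strand_minus, _COMP_IDX[alt_t], alt_t)


def random_sequence(
    length: int,
    composition: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    spectrum: MutationSpectrum | None = None,
) -> str:
    """IID random DNA of a given base composition (or of the stationary
    composition of a spectrum when one is given instead)."""
    rng = rng or np.random.default_rng()
    if spectrum is not None:
        composition = spectrum.stationary_composition()
    p = np.full(4, 0.25) if composition is None else np.asarray(composition, float)
    p = p / p.sum()
    return "".join(np.array(BASES)[rng.choice(4, size=length, p=p)])


@dataclass(frozen=True)
class Bottleneck:
    """Wright-Fisher drift on allele frequencies: ``generations`` rounds of
    binomial resampling at diploid size ``size`` applied to the derived
    lineage (its private variants and its copy of the shared variants)."""

    size: int = 100
    generations: int = 40


@dataclass(frozen=True)
class ModifierConfig:
    """A causal bias-modifier locus.

    Carriers of the modifier allele accrue additional alternative alleles at
    a diffuse set of "effect" sites whose alternative bases are drawn with
    the AT bias multiplied by (1 + delta) — the generative stand-in for a
    DNA-repair polymorphism that shifts the carrier's mutation spectrum
    genome-wide. At an effect site, each allele of a sample with modifier
    dosage d is alternative with probability
    ``effect_base_freq + effect_slope * d``.

    The effect is deliberately spread thin (many sites, small per-site
    slope). An aggregate base-composition phenotype can only carry a
    per-locus association signal if the causal direction's excess genetic
    variance stays below the spiked-eigenvalue detectability edge of the
    SNP panel (~sqrt(m/n) above the bulk): otherwise the modifier direction
    surfaces as a top principal component and is controlled away as
    structure (and the kinship term absorbs it). The achievable squared
    signal-to-noise is proportional to the eigenvalue excess, so recovery
    needs the edge itself to be high: large panels and modest sample
    counts. The defaults are calibrated for ~9e4 SNPs and ~100 samples
    (eigenvalue excess ~15 vs a bulk edge of ~30, aggregate shift ~0.9
    within-group phenotype standard deviations per modifier allele copy);
    for other panel sizes scale ``effect_slope`` by sqrt(9e4 / n_snps).
    """

    delta: float = 11.0
    carrier_freq: float = 0.3
    effect_fraction: float = 0.85
    effect_base_freq: float = 0.2
    effect_slope: float = 0.0065


@dataclass
class PopSimConfig:
    """Study conditions for the two-group population generator.

    Defaults emulate a basal (ancestral-source) group and a derived group
    separated by a bottleneck, genotyped at biallelic SNPs with an AT-biased,
    strand-symmetric spectrum; the derived lineage's private variants are
    drawn from a more AT-biased effective spectrum (``derived_at_boost``),
    the repair-divergence reading of the A&T-increase. ``bottleneck=None``
    gives a panmictic null: one population, all variants shared, groups
    exchangeable.
    """

    n_basal: int = 50
    n_derived: int = 100
    n_snps: int = 10_000
    at_bias: float = 2.0
    derived_at_boost: float = 3.0
    private_fraction: float = 0.4
    bottleneck: Bottleneck | None = field(default_factory=Bottleneck)
    ref_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    sfs_min: float = 0.02
    sfs_max: float = 0.98
    min_maf: float = 0.05
    n_chrom: int = 2
    chrom_length: int = 100_000_000
    modifier: ModifierConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_basal, self.n_derived, self.n_snps) <= 0:
            raise ValueError("sample and SNP counts must be positive")
        if not (0 < self.sfs_min < self.sfs_max < 1):
            raise ValueError("SFS frequency bounds must satisfy 0 < lo < hi < 1")
        if not (0 <= self.private_fraction <= 1):
            raise ValueError("private_fraction must be in [0, 1]")


@dataclass
class PopSim:
    """Simulated population with recorded ground truth."""

    variants: pd.DataFrame  # chrom, pos, id, ref, alt
    genotypes: GenotypeMatrix
    groups: pd.Series  # sample -> 'basal' | 'derived'
    truth: dict


def _sfs_frequency(n: int, rng: np.random.Generator, lo: float, hi: float) -> np.ndarray:
    """Neutral-SFS-shaped frequencies: density proportional to 1/x on [lo, hi]."""
    return lo * (hi / lo) ** rng.random(n)


def _drift(f: np.ndarray, size: int, generations: int, rng: np.random.Generator) -> np.ndarray:
    f = f.copy()
    for _ in range(generations):
        f = rng.binomial(2 * size, f) / (2 * size)
    return f


def simulate_populations(config: PopSimConfig) -> PopSim:
    """Generate the two-group SNP panel.

    Sites are drawn in batches and accepted only when the realized overall
    minor allele frequency is >= ``config.min_maf`` (and the site is
    polymorphic), so the output passes the default polymorphic-site filters.
    Site classes: shared (ancestral frequency in both groups, derived copy
    drifted through the bottleneck), private-basal, private-derived
    (frequency 0 in the other group; the derived lineage's drawn from its
    boosted spectrum and drifted).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_b, n_d = cfg.n_basal, cfg.n_derived
    n = n_b + n_d
    spec_shared = MutationSpectrum.with_at_bias(cfg.at_bias)
    spec_derived = spec_shared.scaled_at_bias(cfg.derived_at_boost)
    ref_comp = np.asarray(cfg.ref_composition, float)
    ref_comp = ref_comp / ref_comp.sum()

    m_modifier = 0
    m_effect = 0
    if cfg.modifier is not None:
        m_effect = int(round(cfg.modifier.effect_fraction * cfg.n_snps))
        m_modifier = 1
    m_regular = cfg.n_snps - m_effect - m_modifier
    if m_regular <= 0:
        raise ValueError(
            "n_snps too small for the configured modifier effect fraction; "
            "increase n_snps or decrease effect_fraction"
        )

    cls_list: list[np.ndarray] = []
    ref_list: list[np.ndarray] = []
    alt_list: list[np.ndarray] = []
    dos_list: list[np.ndarray] = []

    # --- regular sites: accept-loop on realized MAF -------------------------
    accepted = 0
    rounds = 0
    while accepted < m_regular:
        rounds += 1
        if rounds > 200:
            raise ValueError(
                "site acceptance is not converging; the configured frequency law "
                "and MAF threshold are infeasible — widen sfs bounds or lower min_maf"
            )
        k = 2 * (m_regular - accepted) + 200
        if cfg.bottleneck is None:
            cls = np.zeros(k, dtype=np.int8)  # all shared, no drift
        else:
            cls = rng.choice(
                3, size=k,
                p=[1 - cfg.private_fraction, cfg.private_fraction / 2, cfg.private_fraction / 2],
            ).astype(np.int8)
        f0 = _sfs_frequency(k, rng, cfg.sfs_min, cfg.sfs_max)
        f_basal = np.where(cls == 2, 0.0, f0)
        f_derived = np.where(cls == 1, 0.0, f0)
        if cfg.bottleneck is not None:
            drifted = _drift(f_derived, cfg.bottleneck.size, cfg.bottleneck.generations, rng)
            f_derived = np.where(cls != 1, drifted, f_derived)
        ref_idx = rng.choice(4, size=k, p=ref_comp)
        alt_idx = np.empty(k, dtype=np.int64)
        dmask = cls == 2
        alt_idx[~dmask] = _draw_alts(ref_idx[~dmask], spec_shared, rng)
        if dmask.any():
            alt_idx[dmask] = _draw_alts(ref_idx[dmask], spec_derived, rng)
        g_b = rng.binomial(2, np.broadcast_to(f_basal, (n_b, k))).astype(np.int8)
        g_d = rng.binomial(2, np.broadcast_to(f_derived, (n_d, k))).astype(np.int8)
        dos = np.vstack([g_b, g_d])
        p_alt = dos.sum(axis=0) / (2 * n)
        keep = np.where(np.minimum(p_alt, 1 - p_alt) >= cfg.min_maf)[0][: m_regular - accepted]
        accepted += keep.size
        cls_list.append(cls[keep])
        ref_list.append(ref_idx[keep])
        alt_list.append(alt_idx[keep])
        dos_list.append(dos[:, keep])

    truth_modifier: dict | None = None
    if cfg.modifier is not None:
        mod = cfg.modifier
        # modifier locus: same carrier frequency in both groups (within-group variation)
        d_mod = rng.binomial(2, mod.carrier_freq, size=n).astype(np.int8)
        # require both carriers and non-carriers so the locus is testable
        while d_mod.max() == d_mod.min():
            d_mod = rng.binomial(2, mod.carrier_freq, size=n).astype(np.int8)
        ref_mod = rng.choice(4, size=1, p=ref_comp)
        alt_mod = _draw_alts(ref_mod, spec_shared, rng)
        cls_list.append(np.array([3], dtype=np.int8))
        ref_list.append(ref_mod)
        alt_list.append(alt_mod)
        dos_list.append(d_mod[:, None])

        # effect sites: per-allele alt probability rises with modifier dosage;
        # alt bases drawn with the amplified AT bias
        spec_eff = spec_shared.scaled_at_bias(1.0 + mod.delta)
        acc_e = 0
        rounds = 0
        p_site = np.clip(mod.effect_base_freq + mod.effect_slope * d_mod.astype(float),
                         0.0, 0.975)
        while acc_e < m_effect:
            rounds += 1
            if rounds > 200:
                raise ValueError(
                    "modifier effect sites cannot pass the MAF threshold; "
                    "increase effect_base_freq"
                )
            k = 2 * (m_effect - acc_e) + 50
            ref_idx = rng.choice(4, size=k, p=ref_comp)
            alt_idx = _draw_alts(ref_idx, spec_eff, rng)
            dos = rng.binomial(2, np.broadcast_to(p_site[:, None], (n, k))).astype(np.int8)
            p_alt = dos.sum(axis=0) / (2 * n)
            keep = np.where(np.minimum(p_alt, 1 - p_alt) >= cfg.min_maf)[0][: m_effect - acc_e]
            acc_e += keep.size
            cls_list.append(np.full(keep.size, 4, dtype=np.int8))
            ref_list.append(ref_idx[keep])
            alt_list.append(alt_idx[keep])
            dos_list.append(dos[:, keep])

    cls = np.concatenate(cls_list)
    ref_idx = np.concatenate(ref_list)
    alt_idx = np.concatenate(alt_list)
    dosage = np.concatenate(dos_list, axis=1)
    m = cls.size

    # shuffle variant order, then place on chromosomes at sorted positions
    order = rng.permutation(m)
    cls, ref_idx, alt_idx = cls[order], ref_idx[order], alt_idx[order]
    dosage = dosage[:, order]
    chrom_of = rng.integers(0, cfg.n_chrom, size=m)
    pos = np.empty(m, dtype=np.int64)
    chroms = np.empty(m, dtype=object)
    final_order = np.argsort(chrom_of, kind="stable")
    for c in range(cfg.n_chrom):
        on_c = np.where(chrom_of == c)[0]
        p = np.sort(rng.choice(cfg.chrom_length, size=on_c.size, replace=False)) + 1
        pos[on_c] = p
        chroms[on_c] = str(c + 1)
    cls, ref_idx, alt_idx = cls[final_order], ref_idx[final_order], alt_idx[final_order]
    dosage = dosage[:, final_order]
    pos, chroms = pos[final_order], chroms[final_order]

    samples = [f"B{i:04d}" for i in range(n_b)] + [f"D{i:04d}" for i in range(n_d)]
    base_arr = np.array(BASES)
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "id": [f"snp{i}" for i in range(m)],
            "ref": base_arr[ref_idx],
            "alt": base_arr[alt_idx],
        }
    )
    groups = pd.Series(
        ["basal"] * n_b + ["derived"] * n_d, index=pd.Index(samples, name="sample"), name="group"
    )
    origin = np.array(["shared", "private_basal", "private_derived", "modifier", "effect"])[cls]
    variants["origin"] = origin
    modifier_id = None
    if cfg.modifier is not None:
        modifier_id = variants.loc[variants["origin"] == "modifier", "id"].iloc[0]
        truth_modifier = {"id": modifier_id, "delta": cfg.modifier.delta}
    truth = {
        "seed": cfg.seed,
        "at_bias": cfg.at_bias,
        "derived_at_boost": cfg.derived_at_boost,
        "bottleneck": asdict(cfg.bottleneck) if cfg.bottleneck else None,
        "modifier": truth_modifier,
        "n_variants": int(m),
        "origin_counts": pd.Series(origin).value_counts().to_dict(),
    }
    return PopSim(
        variants=variants,
        genotypes=GenotypeMatrix(samples, dosage),
        groups=groups,
        truth=truth,
    )


@dataclass
class MutAccumConfig:
    """Mutation-accumulation experiment: ``n_lines`` lines propagated from a
    single ancestor sequence, each accruing ``mutations_per_line`` independent
    substitutions at uniform positions via the spectrum."""

    genome_length: int = 100_000
    n_lines: int = 10
    mutations_per_line: int = 200
    at_bias: float = 2.0
    # ~50% GC ancestor (microbial-like), far from the AT-biased stationary
    # composition, so the A&T-increase across mutation sites is well resolved
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10000")
        if self.mutations_per_line < 1:
            raise ValueError("mutations_per_line must be >= 1")
        if self.mutations_per_line > self.genome_length:
            raise ValueError("more mutations per line than sites in the genome")


@dataclass
class MutAccumSim:
    ancestor: str
    mutations: pd.DataFrame  # line, chrom, pos, ref, alt
    truth: dict


def simulate_mut_accum(config: MutAccumConfig) -> MutAccumSim:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    spectrum = MutationSpectrum.with_at_bias(cfg.at_bias)
    ancestor = random_sequence(cfg.genome_length, cfg.composition, rng)
    anc_arr = np.frombuffer(ancestor.encode(), dtype="S1").astype("U1")
    base_arr = np.array(BASES)
    rows = []
    for line in range(cfg.n_lines):
        sites = np.sort(rng.choice(cfg.genome_length, size=cfg.mutations_per_line, replace=False))
        refs = anc_arr[sites]
        ref_idx = np.searchsorted(base_arr, refs)
        alt_idx = _draw_alts(ref_idx, spectrum, rng)
        for s, r, a in zip(sites, refs, base_arr[alt_idx]):
            rows.append({"line": f"MA{line:02d}", "chrom": "anc", "pos": int(s) + 1,
                         "ref": str(r), "alt": str(a)})
    mutations = pd.DataFrame(rows)
    truth = {"seed": cfg.seed, "at_bias": cfg.at_bias,
             "composition": list(cfg.composition), "n_lines": cfg.n_lines}
    return MutAccumSim(ancestor=ancestor, mutations=mutations, truth=truth)


def simulate_gene_annotation(
    n_genes: int,
    n_chrom: int,
    chrom_length: int,
    rng: np.random.Generator,
    n_terms: int = 20,
    terms_per_gene: float = 3.0,
    repair_fraction: float = 0.05,
    gene_length: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Synthetic gene map for exercising the enrichment stage.

    Returns (genes, gene_terms, repair_genes): a BED-like gene table
    (0-based half-open), a two-column gene/term assignment table, and the
    synthetic repair-gene list. Purely structural — term labels carry no
    biological meaning.
    """
    chroms = rng.integers(0, n_chrom, size=n_genes)
    starts = rng.integers(0, chrom_length - gene_length, size=n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": (chroms + 1).astype(str),
            "start": starts,
            "end": starts + rng.integers(1_000, gene_length, size=n_genes),
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    term_ids = [f"T{i:04d}" for i in range(n_terms)]
    rows = []
    for g in genes["gene_id"]:
        k = min(n_terms, rng.poisson(terms_per_gene))
        for t in rng.choice(n_terms, size=k, replace=False):
            rows.append({"gene_id": g, "term": term_ids[t]})
    gene_terms = pd.DataFrame(rows)
    n_repair = max(1, int(round(repair_fraction * n_genes)))
    repair = sorted(rng.choice(genes["gene_id"].to_numpy(), size=n_repair, replace=False).tolist())
    return genes, gene_terms, repair


def write_vcf(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal, deterministic plain-text VCF (GT only).

    Dosage 0/1/2 maps to 0/0, 0/1, 1/1; -1 to ./.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polypar-synthetic\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in pd.unique(variants["chrom"]):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        dos = genotypes.dosage
        for j, row in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(gt_str[int(d)] for d in dos[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")
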