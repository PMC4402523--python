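"""Individual-strand base composition at three levels.

1. Sequence level: a 1 Mb sequence drawn at the stationary composition of
   the AT-biased strand-symmetric spectrum satisfies PR2 ([A] ~ [T],
   [G] ~ [C]); its reverse complement has mirrored skews.
2. Polymorphic-site level: per-individual [A]..[T] across the simulated SNP
   panel; PR2 shows up as [A]+[C] ~ 0.5 across individuals, and the derived
   (bottlenecked) group shows the A&T-increase relative to the basal group.
3. Allele-frequency divergence between the groups, the raw material of the
   later scans.

Reads results/sim/ (run 01 first); writes results/composition/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from polypar.poly_composition import (
    FilterConfig,
    allele_freq_divergence,
    base_phenotype,
    group_separation,
    load_variants,
    read_groups,
)
from polypar.seq_composition import (
    composition_table,
    count_bases,
    parity_metrics,
    reverse_complement,
)
from polypar.synthetic_data import MutationSpectrum, random_sequence

SEED = 2026
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "composition"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- 1. sequence-level PR2 ------------------------------------------------
    spec = MutationSpectrum.with_at_bias(2.0)
    seq = random_sequence(1_000_000, rng=np.random.default_rng(SEED), spectrum=spec)
    comps = [count_bases(seq, "stationary_1mb"),
             count_bases(reverse_complement(seq), "revcomp_1mb")]
    table = composition_table(comps)
    table.to_csv(OUT / "sequence_composition.tsv", sep="\t", index=False)
    m = parity_metrics(comps[0])
    print(f"sequence level: PR2 deviation {m.pr2_deviation:.4f} "
          f"(AT skew {m.at_skew:+.4f}, GC skew {m.gc_skew:+.4f}) at 1 Mb")

    # --- 2. polymorphic-site level -------------------------------------------
    sim = ROOT / "results" / "sim" / "default"
    variants, genotypes, report = load_variants(sim / "simulated.vcf", FilterConfig())
    groups = read_groups(sim / "groups.tsv")
    pheno = base_phenotype(variants, genotypes)
    pheno.insert(0, "group", groups.reindex(pheno.index))
    pheno.to_csv(OUT / "phenotype.tsv", sep="\t")
    a_plus_c = (pheno["frac_a"] + pheno["frac_c"]).mean()
    a_minus_t = np.abs(pheno["frac_a"] - pheno["frac_t"]).mean()
    print(f"polymorphic-site level: mean [A]+[C] = {a_plus_c:.4f}, "
          f"mean |[A]-[T]| = {a_minus_t:.4f} across {len(pheno)} individuals")
    sep = group_separation(pheno, groups, basal="basal", derived="derived")
    print(f"A&T-increase: derived-basal mean [A] difference {sep['diff_frac_a']:+.5f} "
          f"(Welch t = {sep['welch_t']:.1f}, p = {sep['p_value']:.2e})")
    sep["summary"].to_csv(OUT / "group_summary.tsv", sep="\t")

    # --- 3. allele-frequency divergence ---------------------------------------
    div = allele_freq_divergence(genotypes, groups, "basal", "derived")
    div = pd.concat([variants[["chrom", "pos", "id", "origin"]]
                     if "origin" in variants else variants[["chrom", "pos", "id"]],
                     div], axis=1)
    div.to_csv(OUT / "allele_freq_divergence.tsv", sep="\t", index=False)
    print(f"allele-frequency divergence: mean {div['divergence'].mean():.3f}, "
          f"95th percentile {div['divergence'].quantile(0.95):.3f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    sys.exit(main())
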