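"""Generate the study's synthetic inputs: a bottleneck-divided population
under the AT-biased strand-symmetric spectrum, a panmictic unbiased null,
and a population with a planted bias-modifier locus (ground truth recorded).

Writes results/sim/{default,null,modifier}/ with VCF, groups TSV and truth
JSON. Later drivers consume these outputs.
"""

import json
import sys
from pathlib import Path

from polypar.synthetic_data import (
    ModifierConfig,
    PopSimConfig,
    simulate_populations,
    write_vcf,
)

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def run(name: str, cfg: PopSimConfig) -> None:
    out = OUT / name
    out.mkdir(parents=True, exist_ok=True)
    pop = simulate_populations(cfg)
    write_vcf(pop.variants, pop.genotypes, out / "simulated.vcf",
              contig_lengths={str(c + 1): cfg.chrom_length for c in range(cfg.n_chrom)})
    pop.groups.to_csv(out / "groups.tsv", sep="\t", header=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(pop.truth, fh, indent=2, default=str)
    oc = pop.truth["origin_counts"]
    print(f"{name}: {len(pop.variants)} SNPs x {pop.genotypes.n_samples} samples; "
          f"origins {oc}")


def main() -> None:
    run("default", PopSimConfig(seed=SEED))
    run("null", PopSimConfig(seed=SEED, at_bias=1.0, bottleneck=None))
    run("modifier", PopSimConfig(seed=SEED, n_basal=33, n_derived=67,
                                 n_snps=90_000, modifier=ModifierConfig()))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    sys.exit(main())
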