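#!/usr/bin/env python
"""Diversity, differentiation, private alleles and the replicate PCA.

Computes pixy-style π per deme (ratio of sums over all sites including
invariant ones), Weir-Cockerham and Hudson F_ST, private-allele counts
with the larger deme subsampled five times to the smaller deme's size,
and 25-replicate random-SNP PCA centroids.
"""

import json
from pathlib import Path

import numpy as np

from radpop import io, popstats

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20_103


def main() -> None:
    gm = io.read_vcf(OUT / "simulated.vcf")
    meta = json.loads((OUT / "simulation_meta.json").read_text())
    # deme labels from the simulated sample naming (d0_* / d1_*)
    gm.pops = np.array([0 if s.startswith("d0") else 1 for s in gm.samples])
    inv = int(meta["invariant_sites"])
    i0, i1 = gm.pop_indices(0), gm.pop_indices(1)

    lines = ["stat\tvalue\tnumerator\tdenominator"]
    for deme, idx in ((0, i0), (1, i1)):
        r = popstats.pi(gm.genotypes, idx, invariant_sites=inv)
        lines.append(f"pi_deme{deme}\t{r.pi:.6g}\t{r.diff_sum:.0f}\t{r.comp_sum:.0f}")
        print(f"pi deme{deme} = {r.pi:.4g}")
    for est in ("wc", "hudson"):
        r = popstats.fst(gm.genotypes, i0, i1, est)
        lines.append(f"fst_{est}\t{r.fst:.6g}\t{r.num_sum:.6g}\t{r.den_sum:.6g}")
        print(f"fst[{est}] = {r.fst:.4g}")
    (OUT / "stats.tsv").write_text("\n".join(lines) + "\n")

    full = popstats.private_alleles(gm.genotypes, i0, i1)
    eq = popstats.equalized_private_alleles(gm.genotypes, i1, i0,
                                           n_sub=len(i0), n_reps=5, seed=SEED)
    print(f"private alleles (NA, PAL): {full}; "
          f"PAL equalised to {len(i0)} diploids: {[a for a, _ in eq]}")
    (OUT / "private_alleles.json").write_text(json.dumps(
        {"full_NA_PAL": full, "equalized_PAL": [a for a, _ in eq]}, indent=2))

    pca = popstats.pca_replicates(gm.genotypes, gm.locus_indices(),
                                  n_reps=25, seed=SEED)
    header = "sample\tpop\tPC1\tPC2"
    rows = [f"{s}\t{p}\t{c[0]:.6g}\t{c[1]:.6g}"
            for s, p, c in zip(gm.samples, gm.pops, pca.centroids)]
    (OUT / "pca_centroids.tsv").write_text(header + "\n" + "\n".join(rows) + "\n")
    pc1 = pca.centroids[:, 0]
    sep = pc1[gm.pops == 0].max() < pc1[gm.pops == 1].min() or \
        pc1[gm.pops == 1].max() < pc1[gm.pops == 0].min()
    print(f"PC1 separates the demes with zero centroid overlap: {sep}")


if __name__ == "__main__":
    main()
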