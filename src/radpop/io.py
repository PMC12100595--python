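"""File formats, run manifests, and the pipeline driver.

The interchange format for genotypes is uncompressed VCF 4.2 with diploid
GT calls ("./." for missing) and one contig per RAD locus; the marker→
locus map is a two-column TSV.  Coordinates are 1-based in files and
0-based in memory, with the conversion localised here.  Three-taxon
alignments travel as FASTA, either one file per locus or a single
multi-locus file whose record ids are ``<locus>|<taxon>``.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalescent import LocusAlignment, SimDataset

__all__ = [
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_locus_map",
    "write_locus_map",
    "filter_missing",
    "dataset_to_genotype_matrix",
    "write_three_taxon_fasta",
    "read_three_taxon_fasta",
    "RunManifest",
    "pipeline_run",
]


@dataclass
class GenotypeMatrix:
    """Samples × biallelic sites with missingness and locus identity.

    ``genotypes`` holds diploid alternate-allele dosages (0/1/2; -1 for a
    missing call).  ``chrom`` carries the locus (contig) name per site.
    """

    genotypes: np.ndarray            # (n_samples, n_sites) int8
    samples: list
    chrom: np.ndarray                # (n_sites,) object/str
    pos: np.ndarray                  # (n_sites,) int64, 0-based
    ref: np.ndarray
    alt: np.ndarray
    pops: np.ndarray | None = None   # (n_samples,) int64 deme labels

    @property
    def n_samples(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.genotypes.shape[1])

    def locus_indices(self) -> np.ndarray:
        """Integer locus index per site, in order of first appearance."""
        _, idx = np.unique(self.chrom, return_inverse=True)
        return idx

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.genotypes[:, idx], list(self.samples),
                              self.chrom[idx], self.pos[idx],
                              self.ref[idx], self.alt[idx], self.pops)

    def pop_indices(self, deme: int) -> np.ndarray:
        if self.pops is None:
            raise ValueError("no population assignments attached")
        return np.flatnonzero(self.pops == deme)


def dataset_to_genotype_matrix(ds: SimDataset) -> GenotypeMatrix:
    chrom = np.array([f"locus_{l:05d}" for l in ds.locus_map], dtype=object)
    n = ds.n_sites
    return GenotypeMatrix(ds.genotypes.copy(), list(ds.sample_names), chrom,
                          (ds.positions - 1).astype(np.int64),
                          np.array(["A"] * n, dtype=object),
                          np.array(["T"] * n, dtype=object),
                          ds.pops.copy())


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write uncompressed VCF 4.2 (diploid GT, './.' missing)."""
    path = Path(path)
    contigs = list(dict.fromkeys(gm.chrom.tolist()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radpop\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for s in range(gm.n_sites):
            gts = "\t".join(_GT[int(g)] for g in gm.genotypes[:, s])
            fh.write(f"{gm.chrom[s]}\t{gm.pos[s] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (biallelic sites only)."""
    from cyvcf2 import VCF

    v = VCF(str(path), gts012=True)
    samples = list(v.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    for var in v:
        if len(var.ALT) != 1:
            continue
        chrom.append(var.CHROM)
        pos.append(var.POS - 1)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        gt = var.gt_types.astype(np.int8)   # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = -1
        rows.append(gt)
    v.close()
    G = (np.array(rows, dtype=np.int8).T if rows
         else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(G, samples, np.array(chrom, dtype=object),
                          np.array(pos, dtype=np.int64),
                          np.array(ref, dtype=object), np.array(alt, dtype=object))


def write_locus_map(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tlocus\n")
        for s in range(gm.n_sites):
            fh.write(f"{gm.chrom[s]}:{gm.pos[s] + 1}\t{gm.chrom[s]}\n")


def read_locus_map(path) -> dict:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            site, locus = line.rstrip("\n").split("\t")
            out[site] = locus
    return out


def filter_missing(gm: GenotypeMatrix, max_missing: float = 0.2) -> GenotypeMatrix:
    """Drop sites whose fraction of missing genotype calls exceeds the
    threshold (fractions computed over diploid calls, vcftools-style)."""
    miss = (gm.genotypes < 0).mean(axis=0)
    return gm.take_sites(np.flatnonzero(miss <= max_missing))


# ---------------------------------------------------------------------------
# FASTA dialects for three-taxon locus sets
# ---------------------------------------------------------------------------

def write_three_taxon_fasta(alignments: list, path, per_locus_dir: bool = False) -> None:
    """Write alignments as one multi-locus FASTA (ids ``locus|taxon``) or,
    with ``per_locus_dir``, one FASTA per locus in a directory."""
    if per_locus_dir:
        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        for al in alignments:
            recs = [SeqRecord(Seq(s), id=t, description="")
                    for t, s in (("A", al.a), ("B", al.b), ("C", al.c))]
            SeqIO.write(recs, d / f"{al.locus_id}.fasta", "fasta")
    else:
        recs = []
        for al in alignments:
            for t, s in (("A", al.a), ("B", al.b), ("C", al.c)):
                recs.append(SeqRecord(Seq(s), id=f"{al.locus_id}|{t}", description=""))
        SeqIO.write(recs, str(path), "fasta")


def read_three_taxon_fasta(path) -> list:
    """Read either dialect back into :class:`LocusAlignment` records."""
    path = Path(path)
    loci: dict[str, dict[str, str]] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.fasta")):
            seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(f), "fasta")}
            loci[f.stem] = seqs
    else:
        for r in SeqIO.parse(str(path), "fasta"):
            locus, _, taxon = r.id.rpartition("|")
            loci.setdefault(locus, {})[taxon] = str(r.seq)
    out = []
    for locus in sorted(loci):
        seqs = loci[locus]
        out.append(LocusAlignment(locus, seqs["A"], seqs["B"], seqs["C"]))
    return out


# ---------------------------------------------------------------------------
# run manifest & pipeline driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline stage bit-identically."""

    command: str
    config: dict
    seeds: dict
    versions: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path) -> None:
        if not self.versions:
            import numba
            import radpop
            self.versions = {"radpop": radpop.__version__,
                             "numpy": np.__version__,
                             "numba": numba.__version__,
                             "python": sys.version.split()[0]}
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def digest_inputs(self, paths) -> None:
        for p in paths:
            p = Path(p)
            if p.is_file():
                self.input_digests[p.name] = _sha256(p)


def pipeline_run(config: dict, outdir, seed: int = 0) -> Path:
    """Chain the stages listed in ``config["stages"]`` on synthetic data.

    Supported stages (in this order): ``simulate``, ``filter``, ``prune``,
    ``sfs``, ``fit``, ``compare``, ``bootstrap``, ``stats``, ``pca``,
    ``d3``.  Each stage reads/writes documented formats under ``outdir``;
    all effective settings and per-stage seeds are echoed into
    ``manifest.json``.  No hidden state crosses stage boundaries.
    """
    from . import coalescent as csim
    from . import demfit, ldprune, models, popstats, sfs
    from .coalescent import LocusConfig, SampleConfig
    from .d3 import bootstrap_test, locus_distances

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["simulate", "filter", "prune", "sfs"])
    seeds = {stage: (seed * 1009 + i * 101) % (2**31 - 1)
             for i, stage in enumerate(stages)}
    manifest = RunManifest("pipeline_run", dict(config), seeds)

    gm = None
    obs = None
    if "simulate" in stages:
        model = models.get_model(config.get("model", "M4"))
        params = models.reference_m4_parameters() if config.get(
            "params", "reference") == "reference" else models.ModelParameters(
                dict(config["params"]))
        sample_config = SampleConfig(tuple(config.get("haploids", (52, 88))))
        locus_config = LocusConfig(
            n_loci=int(config.get("n_loci", 6250)),
            locus_length=int(config.get("locus_length", 312)),
            missing_rate=float(config.get("missing_rate", 0.1)))
        ds = csim.simulate_dataset(model, params, sample_config, locus_config,
                                   seeds["simulate"])
        gm = dataset_to_genotype_matrix(ds)
        write_vcf(gm, outdir / "simulated.vcf")
        write_locus_map(gm, outdir / "locus_map.tsv")
        manifest.config["invariant_sites"] = ds.invariant_site_total
    if gm is None:
        gm = read_vcf(config["vcf"])
    if "filter" in stages:
        gm = filter_missing(gm, float(config.get("max_missing", 0.2)))
        write_vcf(gm, outdir / "filtered.vcf")
    if "prune" in stages:
        kept = ldprune.ld_prune(gm.genotypes, window=int(config.get("window", 50)),
                                r2_max=float(config.get("r2_max", 0.1)),
                                locus_map=gm.locus_indices())
        with open(outdir / "prune_report.tsv", "w") as fh:
            fh.write(f"sites_in\t{gm.n_sites}\nsites_out\t{kept.size}\n")
        gm = gm.take_sites(kept)
        write_vcf(gm, outdir / "pruned.vcf")
    if "sfs" in stages:
        n_proj = tuple(config.get("n_proj", (38, 64)))
        mono = float(config.get("invariant_sites",
                                manifest.config.get("invariant_sites", 0)))
        obs = sfs.build_joint_sfs(gm.genotypes, gm.pops, n_proj,
                                  monomorphic_total=mono)
        sfs.write_sfs(obs, outdir / "joint_sfs.txt")
    if "fit" in stages or "compare" in stages or "bootstrap" in stages:
        if obs is None:
            obs = sfs.read_sfs(config["sfs"])
        priors = models.default_priors()
        fit_kwargs = dict(n_sims=int(config.get("n_sims", 5000)),
                          n_cycles=int(config.get("n_cycles", 12)))
        fit_names = config.get("fit_models", [m.name for m in models.build_model_library()])
        fits = [demfit.run_replicates(models.get_model(name), obs, priors,
                                      n_reps=int(config.get("n_reps", 3)),
                                      seed=seeds.get("fit", 1), **fit_kwargs)
                for name in fit_names]
        if "compare" in stages:
            cmp_res = demfit.compare_models(fits, penalty=float(config.get("penalty", 25)))
            cmp_res.table.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)
        best = min(fits, key=lambda f: f.delta)
        with open(outdir / "best_fit.json", "w") as fh:
            json.dump({"model": best.model_name, "loglik": best.max_est_loglik,
                       "delta": best.delta, "params": best.params.values},
                      fh, indent=2, sort_keys=True)
        if "bootstrap" in stages:
            ci = demfit.parametric_bootstrap(
                models.get_model(best.model_name), best.params, obs, priors,
                n_boot=int(config.get("n_boot", 50)), seed=seeds.get("bootstrap", 2),
                n_cycles=int(config.get("boot_cycles", 6)),
                n_sims=int(config.get("boot_sims", 2000)))
            ci.table.to_csv(outdir / "bootstrap_ci.tsv", sep="\t", index=False)
    if "stats" in stages:
        inv = int(float(config.get("invariant_sites",
                                   manifest.config.get("invariant_sites", 0))))
        lines = []
        for d in np.unique(gm.pops):
            res = popstats.pi(gm.genotypes, gm.pop_indices(d), invariant_sites=inv)
            lines.append(f"pi_deme{d}\t{res.pi:.6g}\t{res.diff_sum}\t{res.comp_sum}")
        for est in ("wc", "hudson"):
            res = popstats.fst(gm.genotypes, gm.pop_indices(0), gm.pop_indices(1), est)
            lines.append(f"fst_{est}\t{res.fst:.6g}\t{res.num_sum:.6g}\t{res.den_sum:.6g}")
        (outdir / "stats.tsv").write_text(
            "stat\tvalue\tnumerator\tdenominator\n" + "\n".join(lines) + "\n")
    if "pca" in stages:
        pca = popstats.pca_replicates(gm.genotypes, gm.locus_indices(),
                                      n_reps=int(config.get("pca_reps", 25)),
                                      seed=seeds.get("pca", 3))
        np.savetxt(outdir / "pca_centroids.tsv", pca.centroids, delimiter="\t")
    if "d3" in stages:
        aligns = read_three_taxon_fasta(config["fasta"])
        dist = locus_distances(aligns)
        res = bootstrap_test(dist["d_AC"].to_numpy(), dist["d_BC"].to_numpy(),
                             n_boot=int(config.get("n_boot_d3", 10_000)),
                             seed=seeds.get("d3", 4))
        (outdir / "d3.tsv").write_text(
            "d3\tmean_d_AC\tmean_d_BC\tn_loci\tp_value\n"
            f"{res.d3:.6g}\t{res.mean_ac:.6g}\t{res.mean_bc:.6g}\t"
            f"{res.n_loci}\t{res.p_value:.6g}\n")
    manifest.write(outdir / "manifest.json")
    return outdir
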