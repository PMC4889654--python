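"""Synthetic genotype fixtures with analytically known LD decay and Fst.

The generator produces VCF / GFF3 / population-map / mock selection-scan
fixtures with a machine-readable truth file, so every downstream stage of the
pipeline can be tested against known ground truth.

LD model
--------
Haplotypes are built by a first-order copying chain along each contig: the
allele at site *j* is copied from site *j-1* with probability
``retention_per_bp ** d`` (*d* = inter-site distance in bp), otherwise it is
redrawn from the site's population allele frequency. For sites at allele
frequency 0.5, the expected r^2 between sites at distance *d* is
``retention_per_bp ** (2 d)``, so the model has a closed-form half-decay
distance::

    d_half = ln(2) / (2 * ln(1 / retention_per_bp))

Population structure follows the Balding–Nichols construction: per-population
allele frequencies are Beta-distributed around the ancestral frequency with
variance scaled by the target Fst, so the expected Weir–Cockerham Fst over
many sites approximates ``fst_target``.

Planted signals: ``n_spiked_pairs`` near-perfect-LD site pairs (one site's
alleles duplicated at a second position with 1% independent flips) and
``n_spiked_diff_sites`` sites with an extreme between-population frequency
difference; both kinds receive top-rank alpha values in the mock
selection-scan table, and a gene is planted at a known offset from each
spiked site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults give a small structured panel.

    ``retention_per_bp`` is the per-bp allele-identity retention of the
    copying chain (strictly in (0,1)); ``fst_target`` is on the
    Weir–Cockerham scale. The same seed and config always produce
    byte-identical output files.
    """

    n_populations: int = 3
    n_samples_per_pop: int = 18
    n_contigs: int = 4
    contig_length: int = 10_000
    snp_spacing: int = 50
    retention_per_bp: float = 0.99943
    fst_target: float = 0.10
    missing_rate: float = 0.05
    depth_mean: float = 40.0
    maf_floor: float = 0.05
    n_spiked_pairs: int = 3
    n_spiked_diff_sites: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.retention_per_bp < 1.0:
            raise ValueError("retention_per_bp must be strictly in (0, 1)")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("n_populations", "n_samples_per_pop", "n_contigs",
                     "contig_length", "snp_spacing", "n_spiked_pairs",
                     "n_spiked_diff_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def true_half_decay_bp(self) -> float:
        """Closed-form LD half-decay distance of the copying chain, in bp."""
        return math.log(2.0) / (2.0 * math.log(1.0 / self.retention_per_bp))


POP_NAMES = ("MS", "OT", "NB", "KG", "P4", "P5", "P6", "P7")


@dataclass
class HaplotypePanel:
    """2N haplotypes per population at shared sites.

    ``haplotypes`` is (2 * n_samples_total) x n_sites with alleles in {0,1};
    haplotypes 2i, 2i+1 belong to diploid sample i. ``pop_freqs`` is
    n_populations x n_sites. ``spiked_pairs`` / ``spiked_diff_sites`` record
    planted-signal site indices.
    """

    sites: pd.DataFrame              # contig, pos
    ancestral_freq: np.ndarray       # (n_sites,)
    pop_freqs: np.ndarray            # (n_pops, n_sites)
    haplotypes: np.ndarray           # (2*N, n_sites) int8
    sample_pops: np.ndarray          # (N,) population index per sample
    spiked_pairs: list[tuple[int, int]]
    spiked_diff_sites: list[int]

    @property
    def n_samples(self) -> int:
        return len(self.sample_pops)

    def dosages(self) -> np.ndarray:
        """Diploid ALT dosage matrix, samples x sites."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)


def _site_positions(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(cfg.n_contigs):
        name = f"contig{c + 1}"
        n_draw = int(2 * cfg.contig_length / cfg.snp_spacing) + 10
        gaps = rng.geometric(1.0 / cfg.snp_spacing, size=n_draw)
        pos = 1 + np.cumsum(gaps)
        pos = pos[pos <= cfg.contig_length]
        for p in pos:
            rows.append((name, int(p)))
    if not rows:
        raise ValueError("degenerate config: no sites fall within the contigs")
    return pd.DataFrame(rows, columns=["contig", "pos"])


def _draw_ancestral(cfg: SimConfig, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    # truncated-uniform spectrum: keeps MAF-filter survivors downstream
    lo = max(cfg.maf_floor, 0.01) + 0.02
    return rng.uniform(lo, 1.0 - lo, size=n_sites)


def _copying_chain(sites: pd.DataFrame, freqs: np.ndarray, n_haplotypes: int,
                   retention: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate haplotypes site by site along each contig.

    Each haplotype carries a latent uniform that is retained from the
    previous site with probability ``retention ** d`` and redrawn otherwise;
    the allele at site j is the indicator ``u < freqs[j]``. Retaining the
    generating uniform (rather than the allele) keeps every site's marginal
    frequency exactly at ``freqs[j]`` — so population differentiation is
    preserved — while sites sharing the uniform are comonotone, giving
    r^2 = retention^(2d) between frequency-0.5 sites at distance d.
    """
    n_sites = len(sites)
    haps = np.empty((n_haplotypes, n_sites), dtype=np.int8)
    contigs = sites["contig"].to_numpy()
    pos = sites["pos"].to_numpy()
    u = rng.random(n_haplotypes)
    prev_contig = None
    for j in range(n_sites):
        fresh = rng.random(n_haplotypes)
        if contigs[j] != prev_contig:
            u = fresh
        else:
            d = pos[j] - pos[j - 1]
            keep = rng.random(n_haplotypes) < retention ** d
            u = np.where(keep, u, fresh)
        haps[:, j] = (u < freqs[j]).astype(np.int8)
        prev_contig = contigs[j]
    return haps


def simulate_haplotypes(cfg: SimConfig) -> HaplotypePanel:
    """Simulate an unstructured panel (all populations share site frequencies).

    Raises on degenerate configs (zero samples or zero sites).
    """
    if cfg.n_populations < 1 or cfg.n_samples_per_pop < 1:
        raise ValueError("need at least one population with at least one sample")
    if cfg.n_contigs < 1 or cfg.contig_length < 1:
        raise ValueError("need at least one contig of positive length")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    sites = _site_positions(cfg, rng)
    anc = _draw_ancestral(cfg, len(sites), rng)
    n_samples = cfg.n_populations * cfg.n_samples_per_pop
    haps = _copying_chain(sites, anc, 2 * n_samples, cfg.retention_per_bp, rng)
    pop_freqs = np.tile(anc, (cfg.n_populations, 1))
    sample_pops = np.repeat(np.arange(cfg.n_populations), cfg.n_samples_per_pop)
    return HaplotypePanel(sites, anc, pop_freqs, haps, sample_pops, [], [])


def apply_structure(panel: HaplotypePanel, cfg: SimConfig) -> HaplotypePanel:
    """Re-simulate the panel under Balding–Nichols population structure.

    Per-population frequencies are drawn Beta(p(1-F)/F, (1-p)(1-F)/F) around
    the panel's ancestral frequencies; with ``fst_target == 0`` populations
    share the ancestral frequencies exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    anc = panel.ancestral_freq
    F = cfg.fst_target
    if F == 0.0:
        pop_freqs = np.tile(anc, (cfg.n_populations, 1))
    else:
        scale = (1.0 - F) / F
        pop_freqs = rng.beta(anc * scale, (1.0 - anc) * scale,
                             size=(cfg.n_populations, len(anc)))
        pop_freqs = np.clip(pop_freqs, 1e-6, 1.0 - 1e-6)
    n_hap_per_pop = 2 * cfg.n_samples_per_pop
    blocks = [
        _copying_chain(panel.sites, pop_freqs[k], n_hap_per_pop,
                       cfg.retention_per_bp, rng)
        for k in range(cfg.n_populations)
    ]
    haps = np.vstack(blocks)
    sample_pops = np.repeat(np.arange(cfg.n_populations), cfg.n_samples_per_pop)
    return HaplotypePanel(panel.sites.copy(), anc.copy(), pop_freqs, haps,
                          sample_pops, list(panel.spiked_pairs),
                          list(panel.spiked_diff_sites))


SPIKE_MIN_DISTANCE = 2000   # bp; far beyond the default half-decay (~608 bp)
SPIKE_MAX_DISTANCE = 8000


def spike_signals(panel: HaplotypePanel, cfg: SimConfig) -> HaplotypePanel:
    """Plant near-perfect-LD pairs and extreme-differentiation sites.

    Each spiked pair duplicates a donor site's alleles onto a *distant*
    same-contig site (2–8 kb away) with 1% independent flips: near-1 r^2
    without degeneracy, at a distance where background LD has decayed to
    near zero — the abnormal-LD signal the outlier test is meant to find.
    Each spiked differentiation site gets near-fixed opposite alleles in
    alternating populations.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    sites = panel.sites
    haps = panel.haplotypes.copy()
    pop_freqs = panel.pop_freqs.copy()
    n_hap = haps.shape[0]

    contigs = sites["contig"].to_numpy()
    pos = sites["pos"].to_numpy()
    donors = rng.permutation(len(sites))
    # mid-frequency donors only, so planted pairs survive the MAF filter
    freq = haps.mean(axis=0)

    spiked_pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for j in donors:
        if len(spiked_pairs) >= cfg.n_spiked_pairs:
            break
        if j in used or not 0.15 <= freq[j] <= 0.85:
            continue
        dist = np.abs(pos - pos[j])
        ok = np.flatnonzero(
            (contigs == contigs[j]) & (dist >= SPIKE_MIN_DISTANCE)
            & (dist <= SPIKE_MAX_DISTANCE)
        )
        ok = np.array([k for k in ok if k not in used and k != j])
        if len(ok) == 0:
            continue
        k = int(rng.choice(ok))
        flips = rng.random(n_hap) < 0.01
        haps[:, k] = np.where(flips, 1 - haps[:, j], haps[:, j])
        pop_freqs[:, k] = pop_freqs[:, j]
        a, b = (int(j), k) if j < k else (k, int(j))
        spiked_pairs.append((a, b))
        used.update((int(j), k))

    remaining = [j for j in range(len(sites)) if j not in used]
    rng.shuffle(remaining)
    spiked_diff: list[int] = []
    n_pops = pop_freqs.shape[0]
    for j in remaining[: cfg.n_spiked_diff_sites]:
        for k in range(n_pops):
            f = 0.98 if k % 2 == 0 else 0.02
            pop_freqs[k, j] = f
            sel = np.flatnonzero(np.repeat(panel.sample_pops == k, 2))
            haps[sel, j] = (rng.random(sel.size) < f).astype(np.int8)
        spiked_diff.append(int(j))

    return HaplotypePanel(sites.copy(), panel.ancestral_freq.copy(), pop_freqs,
                          haps, panel.sample_pops.copy(), spiked_pairs,
                          sorted(spiked_diff))


def simulate(cfg: SimConfig) -> HaplotypePanel:
    """Full generator: copying chain -> population structure -> planted signals."""
    return spike_signals(apply_structure(simulate_haplotypes(cfg), cfg), cfg)


def _sample_names(cfg: SimConfig) -> list[str]:
    return [
        f"{POP_NAMES[k]}_{i + 1:03d}"
        for k in range(cfg.n_populations)
        for i in range(cfg.n_samples_per_pop)
    ]


GENE_OFFSET_BP = 300   # gap between a spiked site and its planted gene
GENE_LENGTH_BP = 500


def emit_fixtures(panel: HaplotypePanel, cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, GFF3, population map, mock alpha table, and truth file.

    Returns a dict of the written paths. Low-depth and missing genotypes are
    written as-is (``./.``) so the downstream filters are actually exercised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))

    dos = panel.dosages()
    n_samples, n_sites = dos.shape
    depth = rng.poisson(cfg.depth_mean, size=dos.shape).astype(np.int32)
    missing = rng.random(dos.shape) < cfg.missing_rate
    sample_ids = _sample_names(cfg)

    paths = {
        "vcf": out / "sim.vcf",
        "gff": out / "genes.gff3",
        "popmap": out / "popmap.tsv",
        "alpha": out / "alpha_table.txt",
        "truth": out / "truth.tsv",
    }

    bases = ("A", "C", "G", "T")
    refalt = [
        (bases[i % 4], bases[(i % 4 + 1 + i // 4 % 3) % 4]) for i in range(n_sites)
    ]
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=radpop-simulate\n")
        for c in range(cfg.n_contigs):
            fh.write(f"##contig=<ID=contig{c + 1},length={cfg.contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        contig_col = panel.sites["contig"].to_numpy()
        pos_col = panel.sites["pos"].to_numpy()
        for j in range(n_sites):
            ref, alt = refalt[j]
            fields = [contig_col[j], str(int(pos_col[j])), ".", ref, alt,
                      ".", "PASS", ".", "GT:DP"]
            for i in range(n_samples):
                gt = "./." if missing[i, j] else gt_str[int(dos[i, j])]
                fields.append(f"{gt}:{int(depth[i, j])}")
            fh.write("\t".join(fields) + "\n")

    # gene track: one gene per spiked site, at a fixed known offset downstream
    gene_rows = []
    gid = 0
    spiked_sites = sorted({j for pair in panel.spiked_pairs for j in pair}
                          | set(panel.spiked_diff_sites))
    for j in spiked_sites:
        contig = panel.sites["contig"].iloc[j]
        pos = int(panel.sites["pos"].iloc[j])
        start = pos + GENE_OFFSET_BP   # signed SNP->gene distance == GENE_OFFSET_BP
        end = start + GENE_LENGTH_BP - 1
        gid += 1
        gene_rows.append((contig, start, end, f"SIMGENE{gid:04d}", j))
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, start, end, name, _ in gene_rows:
            fh.write(f"{contig}\tradpop_sim\tgene\t{start}\t{end}\t.\t+\t.\t"
                     f"ID={name};Name={name}\n")

    with open(paths["popmap"], "w") as fh:
        for i, sid in enumerate(sample_ids):
            pop = POP_NAMES[panel.sample_pops[i]]
            pheno = "infected" if i % 2 == 0 else "uninfected"
            fh.write(f"{sid}\t{pop}\t{pheno}\n")

    # mock selection-scan table in the BayeScan _fst.txt dialect; spiked
    # sites get the largest alpha values (top ranks)
    alpha = rng.normal(0.0, 0.3, size=n_sites)
    fst_col = np.abs(rng.normal(0.05, 0.02, size=n_sites))
    qval = rng.uniform(0.2, 1.0, size=n_sites)
    for rank, j in enumerate(spiked_sites):
        alpha[j] = 2.5 + 0.1 * rank
        qval[j] = 0.001
    with open(paths["alpha"], "w") as fh:
        fh.write("  prob log10(PO) qval alpha fst\n")
        for j in range(n_sites):
            prob = 1.0 - qval[j] * 0.5
            fh.write(f"{j + 1}  {prob:.5f} {np.log10(prob / (1 - prob) + 1e-9):.5f} "
                     f"{qval[j]:.5f} {alpha[j]:.5f} {fst_col[j]:.5f}\n")

    with open(paths["truth"], "w") as fh:
        fh.write("kind\tcontig\tpos_a\tpos_b\tkey\tvalue\n")
        for key, value in asdict(cfg).items():
            fh.write(f"param\t.\t.\t.\t{key}\t{value}\n")
        fh.write(f"param\t.\t.\t.\ttrue_half_decay_bp\t{cfg.true_half_decay_bp:.4f}\n")
        for a, b in panel.spiked_pairs:
            fh.write("spiked_pair\t{}\t{}\t{}\t.\t.\n".format(
                panel.sites['contig'].iloc[a],
                int(panel.sites['pos'].iloc[a]),
                int(panel.sites['pos'].iloc[b])))
        for j in panel.spiked_diff_sites:
            fh.write("spiked_diff_site\t{}\t{}\t.\t.\t.\n".format(
                panel.sites['contig'].iloc[j], int(panel.sites['pos'].iloc[j])))
        for contig, start, end, name, j in gene_rows:
            fh.write(f"gene\t{contig}\t{start}\t{end}\tsite_index\t{j}\n")
    return paths


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
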