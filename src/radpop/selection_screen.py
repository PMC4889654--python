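"""Selection-candidate screen: outlier-rank SNPs x LD-flagged pairs x genes.

Parses a BayeScan-style per-SNP table (columns including ``alpha``, ``fst``,
``qval``; rows in the same order as the matched site list), takes the top
alpha fraction (ties at the cutoff included), keeps those that belong to at
least one LD-flagged pair, and reports genes whose interval lies within a
window (default 1000 bp, boundary inclusive) of each candidate SNP, plus
candidates shared across labelled comparisons.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import pyranges as pr


def read_alpha_table(path: str, sites: pd.DataFrame) -> pd.DataFrame:
    """Read a whitespace-delimited per-SNP scan table and map rows to sites.

    ``sites`` must carry ``contig`` and ``pos`` in the scan's row order;
    a row-count mismatch is a hard error (the scan reports loci by index).
    """
    tab = pd.read_csv(path, sep=r"\s+")
    if "alpha" not in tab.columns:
        raise ValueError(f"no 'alpha' column in {path} (columns: {list(tab.columns)})")
    if len(tab) != len(sites):
        raise ValueError(
            f"alpha table has {len(tab)} rows but site list has {len(sites)}"
        )
    out = sites[["contig", "pos"]].reset_index(drop=True).copy()
    for col in ("alpha", "fst", "qval"):
        if col in tab.columns:
            out[col] = tab[col].to_numpy()
    return out


def top_alpha(records: pd.DataFrame, fraction: float = 0.10,
              use_abs: bool = False) -> pd.DataFrame:
    """SNPs in the top ``fraction`` of alpha values, cutoff ties included.

    The cutoff is the k-th largest alpha with ``k = ceil(fraction * m)``;
    every SNP with alpha >= cutoff is returned, so ties straddling the
    boundary can push the set above k. ``use_abs`` ranks on \\|alpha\\|.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    vals = records["alpha"].abs() if use_abs else records["alpha"]
    m = len(records)
    k = max(1, math.ceil(fraction * m))
    cutoff = np.sort(vals.to_numpy())[::-1][k - 1]
    out = records[vals >= cutoff].copy()
    out["rank_percentile"] = vals.rank(pct=True, ascending=False)[out.index]
    return out


def intersect_ld(top_snps: pd.DataFrame, flagged_pairs: pd.DataFrame) -> pd.DataFrame:
    """Keep top-ranked SNPs that belong to >= 1 LD-flagged pair.

    Each candidate is annotated with its best partner: the other member of
    the flagged pair with the smallest adjusted probability.
    """
    flagged = flagged_pairs[flagged_pairs["flagged"]] if "flagged" in flagged_pairs else flagged_pairs
    if len(flagged) == 0 or len(top_snps) == 0:
        return top_snps.iloc[0:0].assign(partner_pos=pd.Series(dtype=int),
                                         partner_p_adj=pd.Series(dtype=float))
    # long form: one row per (member snp, partner snp) of each flagged pair
    half_a = flagged[["contig", "pos_a", "pos_b", "p_adj"]].rename(
        columns={"pos_a": "pos", "pos_b": "partner_pos"})
    half_b = flagged[["contig", "pos_b", "pos_a", "p_adj"]].rename(
        columns={"pos_b": "pos", "pos_a": "partner_pos"})
    members = pd.concat([half_a, half_b], ignore_index=True)
    best = (members.sort_values("p_adj", kind="stable")
                   .drop_duplicates(["contig", "pos"])
                   .rename(columns={"p_adj": "partner_p_adj"}))
    out = top_snps.merge(best, on=["contig", "pos"], how="inner")
    return out.reset_index(drop=True)


def read_gff(path: str) -> pd.DataFrame:
    """Read gene features from a GFF3 into contig/start/end/strand/gene_id."""
    gr = pr.read_gff3(str(path)).df
    genes = gr[gr["Feature"] == "gene"].copy()
    id_col = "ID" if "ID" in genes.columns else ("Name" if "Name" in genes.columns else None)
    out = pd.DataFrame({
        "contig": genes["Chromosome"].astype(str),
        # pyranges converts GFF3 to 0-based half-open; back to 1-based inclusive
        "start": genes["Start"].astype(int) + 1,
        "end": genes["End"].astype(int),
        "strand": genes.get("Strand", "."),
        "gene_id": genes[id_col].astype(str) if id_col else [f"gene{i}" for i in range(len(genes))],
    })
    return out.reset_index(drop=True)


def genes_near(snps: pd.DataFrame, genes: pd.DataFrame, window: int = 1000) -> pd.DataFrame:
    """Genes whose interval lies within ``window`` bp of each SNP (inclusive).

    Distance is 0 for a SNP inside the gene; otherwise the signed gap:
    positive when the gene starts downstream of the SNP, negative when it
    ends upstream. Strand never affects the distance. SNP contigs absent
    from the gene track produce no hits (with a warning).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    missing = set(snps["contig"]) - set(genes["contig"])
    if missing:
        warnings.warn(f"contigs with SNPs but no gene annotation: {sorted(missing)}",
                      stacklevel=2)
    rows = []
    by_contig = {c: g for c, g in genes.groupby("contig")}
    for _, snp in snps.iterrows():
        g = by_contig.get(snp["contig"])
        if g is None:
            continue
        pos = int(snp["pos"])
        start = g["start"].to_numpy()
        end = g["end"].to_numpy()
        dist = np.where(pos < start, start - pos,
                        np.where(pos > end, -(pos - end), 0))
        hit = np.abs(dist) <= window
        for k in np.flatnonzero(hit):
            rows.append({**{c: snp[c] for c in snps.columns},
                         "gene_id": g["gene_id"].iloc[k],
                         "gene_start": int(start[k]),
                         "gene_end": int(end[k]),
                         "distance": int(dist[k])})
    cols = list(snps.columns) + ["gene_id", "gene_start", "gene_end", "distance"]
    return pd.DataFrame(rows, columns=cols)


def shared_outliers(candidate_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """SNPs (keyed contig:pos) present in >= 2 labelled candidate sets."""
    if len(candidate_sets) < 2:
        raise ValueError("need >= 2 labelled candidate sets")
    keyed: dict[str, set[tuple[str, int]]] = {
        label: {(str(r.contig), int(r.pos)) for r in df.itertuples()}
        for label, df in candidate_sets.items()
    }
    counts: dict[tuple[str, int], list[str]] = {}
    for label, keys in keyed.items():
        for key in keys:
            counts.setdefault(key, []).append(label)
    rows = [
        {"contig": c, "pos": p, "n_comparisons": len(labels),
         "comparisons": ",".join(sorted(labels))}
        for (c, p), labels in counts.items() if len(labels) >= 2
    ]
    out = pd.DataFrame(rows, columns=["contig", "pos", "n_comparisons", "comparisons"])
    return out.sort_values(["contig", "pos"]).reset_index(drop=True)


def screen(
    alpha_records: pd.DataFrame,
    flagged_pairs: pd.DataFrame,
    genes: pd.DataFrame,
    comparison: str,
    fraction: float = 0.10,
    window: int = 1000,
    use_abs: bool = False,
) -> pd.DataFrame:
    """Full screen for one comparison: rank -> LD intersect -> nearby genes."""
    top = top_alpha(alpha_records, fraction=fraction, use_abs=use_abs)
    cand = intersect_ld(top, flagged_pairs)
    if len(cand) == 0:
        report = cand.assign(gene_id=pd.Series(dtype=str),
                             gene_start=pd.Series(dtype=int),
                             gene_end=pd.Series(dtype=int),
                             distance=pd.Series(dtype=int))
    else:
        hits = genes_near(cand, genes, window=window)
        report = cand.merge(hits[["contig", "pos", "gene_id", "gene_start",
                                  "gene_end", "distance"]],
                            on=["contig", "pos"], how="left")
    report["comparison"] = comparison
    return report
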