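"""Imprinting ~ expression correlation network (IEN) and related scoring.

The IEN asks which cell types carry a gene's parent-of-origin expression
bias: across bulk RNA-seq replicates, the focal gene's per-replicate
imprinting signal (maternal minus paternal allele expression) is correlated
with the expression of cell-type marker genes; the signs of those
correlations are tallied per cell-type category and tested for dependence
with a chi-square (no continuity correction).  A positive-sign enrichment in
a category links the maternal-allele bias to that cell type.

Also here: mean-expression profiles of genes across annotated single cells,
Ward.D2 grouping of imprinted-gene profiles, and per-brain-region Fisher
scoring of reciprocal-cross reporter-image tallies (a region is called
maternally imprinted only when both reporter channels agree, p < 0.05 in the
maternal-consistent direction in both crosses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .stats import fisher_exact

__all__ = [
    "AllelicExpressionMatrix",
    "MarkerSet",
    "imprinting_signal",
    "marker_correlations",
    "sign_tally_chisq",
    "celltype_mean_expression",
    "cluster_imprinted_genes",
    "region_imprinting_fisher",
]


@dataclass
class AllelicExpressionMatrix:
    """Parent-resolved allelic expression of a focal gene plus marker genes.

    ``maternal`` / ``paternal`` are per-replicate allele expression of the
    focal gene (already resolved from the reciprocal-cross orientation);
    ``markers`` is a replicates x genes total-expression table.
    """

    maternal: pd.Series
    paternal: pd.Series
    markers: pd.DataFrame
    replicate_cross: pd.Series | None = None  # "initial" | "reciprocal"

    def __post_init__(self):
        if not self.maternal.index.equals(self.paternal.index):
            raise ValueError("maternal/paternal replicate indexes differ")
        if (self.maternal < 0).any() or (self.paternal < 0).any():
            raise ValueError("allelic expression must be non-negative")
        if len(self.maternal) < 3:
            raise ValueError("need >= 3 replicates for correlation analysis")


@dataclass
class MarkerSet:
    """Marker gene -> cell-type category map (each marker in one category)."""

    categories: dict  # gene -> category label

    def __post_init__(self):
        if not self.categories:
            raise ValueError("empty marker set")

    def genes(self, category=None):
        if category is None:
            return list(self.categories)
        return [g for g, c in self.categories.items() if c == category]

    @property
    def category_names(self):
        return sorted(set(self.categories.values()))


def imprinting_signal(m: AllelicExpressionMatrix) -> pd.Series:
    """Per-replicate maternal - paternal expression of the focal gene."""
    if m.maternal.isna().any() or m.paternal.isna().any():
        raise ValueError("missing allelic data in some replicate")
    return m.maternal - m.paternal


def marker_correlations(signal: pd.Series, m: AllelicExpressionMatrix,
                        markers: MarkerSet) -> tuple[pd.Series, list]:
    """Pearson r of the imprinting signal with each marker's expression.

    Returns (r per marker, skipped zero-variance markers)."""
    skipped = []
    rs = {}
    sig = signal.loc[m.markers.index]
    for gene in markers.genes():
        if gene not in m.markers.columns:
            skipped.append(gene)
            continue
        x = m.markers[gene].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(sig.to_numpy(dtype=float)) == 0:
            skipped.append(gene)
            continue
        rs[gene] = float(sps.pearsonr(sig.to_numpy(dtype=float), x)[0])
    return pd.Series(rs), skipped


def sign_tally_chisq(rs: pd.Series, markers: MarkerSet):
    """Tally correlation signs per category; chi-square test of independence.

    Markers with r exactly 0 are excluded (and counted).  Returns a dict
    with the categories x {positive, negative} table, the chi-square
    statistic and p (no continuity correction), Pearson residuals
    (obs - exp)/sqrt(exp), and the number of zero-r exclusions.
    """
    zeros = [g for g in rs.index if rs[g] == 0]
    rs = rs[rs != 0]
    cats = [c for c in markers.category_names
            if any(markers.categories.get(g) == c for g in rs.index)]
    if len(cats) < 2:
        raise ValueError("need signed markers in >= 2 categories")
    table = pd.DataFrame(0, index=cats, columns=["positive", "negative"])
    for g in rs.index:
        c = markers.categories.get(g)
        if c is None:
            continue
        table.loc[c, "positive" if rs[g] > 0 else "negative"] += 1
    obs = table.to_numpy(dtype=float)
    chi2, p, _, expected = sps.chi2_contingency(obs, correction=False)
    residuals = pd.DataFrame((obs - expected) / np.sqrt(expected),
                             index=table.index, columns=table.columns)
    small = bool((expected < 5).any())
    return {
        "table": table,
        "chi2": float(chi2),
        "p": float(p),
        "residuals": residuals,
        "n_zero_excluded": len(zeros),
        "small_expected_counts": small,
    }


def celltype_mean_expression(cells: pd.DataFrame, labels) -> pd.DataFrame:
    """Mean expression of each gene across all cells of each type.

    ``cells`` is cells x genes; ``labels`` assigns each cell a type.
    Returns genes x cell-types.  Empty types are dropped.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=cells.index)
    if labels.isna().any():
        raise ValueError("every cell must be labeled")
    return cells.groupby(labels).mean().T


def cluster_imprinted_genes(means: pd.DataFrame, n_groups: int = 24) -> pd.Series:
    """Group genes by Ward.D2 on Euclidean distances of cell-type profiles."""
    if n_groups > len(means):
        raise ValueError("n_groups exceeds the number of genes")
    if len(means) < 2:
        raise ValueError("need >= 2 genes")
    Z = linkage(means.to_numpy(dtype=float), method="ward")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    return pd.Series(labels, index=means.index, name="group")


# --- reciprocal-cross reporter-image scoring --------------------------------

#: which cross carries the maternal copy of each reporter channel
MATERNAL_CROSS = {"GFP": "GFP/V5", "V5": "V5/GFP"}


def region_imprinting_fisher(tallies: pd.DataFrame, min_images: int = 8,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per-region Fisher scoring of allele-dominant reporter images.

    ``tallies`` columns: region, cross ("GFP/V5" or "V5/GFP"), channel
    ("GFP" or "V5"), images_with_dominant, images_total.  Per region and
    channel, a 2x2 Fisher compares dominant-image frequency between the two
    crosses; the signed score is -log10(p), positive when the dominance is
    maternal-consistent (dominant expression from the channel that is
    maternal in that cross).  A region is called maternally imprinted iff
    both channels are significant in the maternal direction.  Regions with
    fewer than ``min_images`` per cross are flagged untested.
    """
    rows = []
    for region, sub in tallies.groupby("region"):
        row = {"region": region, "tested": True, "maternal_call": False}
        for channel in ("GFP", "V5"):
            ch = sub[sub["channel"] == channel].set_index("cross")
            if not {"GFP/V5", "V5/GFP"}.issubset(ch.index):
                row["tested"] = False
                continue
            if (ch["images_total"] < min_images).any():
                row["tested"] = False
                continue
            if (ch["images_with_dominant"] > ch["images_total"]).any():
                raise ValueError(f"{region}: dominant tally exceeds image total")
            t = np.array([
                [ch.loc["GFP/V5", "images_with_dominant"],
                 ch.loc["GFP/V5", "images_total"]
                 - ch.loc["GFP/V5", "images_with_dominant"]],
                [ch.loc["V5/GFP", "images_with_dominant"],
                 ch.loc["V5/GFP", "images_total"]
                 - ch.loc["V5/GFP", "images_with_dominant"]],
            ])
            res = fisher_exact(t)
            # dominance direction: which cross shows more dominant images
            f_gfpv5 = t[0, 0] / t[0].sum()
            f_v5gfp = t[1, 0] / t[1].sum()
            dominant_cross = "GFP/V5" if f_gfpv5 >= f_v5gfp else "V5/GFP"
            maternal = MATERNAL_CROSS[channel] == dominant_cross
            score = -np.log10(max(res.p, 1e-300))
            row[f"{channel.lower()}_p"] = res.p
            row[f"{channel.lower()}_score"] = score if maternal else -score
        if row["tested"]:
            row["maternal_call"] = bool(
                row.get("gfp_p", 1.0) < alpha and row.get("v5_p", 1.0) < alpha
                and row.get("gfp_score", -1) > 0 and row.get("v5_score", -1) > 0
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")
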