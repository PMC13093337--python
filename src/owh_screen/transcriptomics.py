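"""Targeted-panel expression analyses: normalization, differential expression,
PCA with 95%-variance component selection, top contributors, Venn partitions,
the combination-only normalization filter, and hypergeometric gene-set
enrichment."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests


def normalize_expression(raw: pd.DataFrame,
                         housekeeping: list | None = None) -> pd.DataFrame:
    """Geometric-mean scale each sample, then log2(count + 1).

    Each sample (column) is divided by the geometric mean of its housekeeping
    transcripts (all transcripts when none are given), making the output
    invariant to global per-sample scaling.  An all-zero sample is an error.
    """
    counts = raw.astype(float)
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    if ((counts == 0).all(axis=0)).any():
        bad = counts.columns[(counts == 0).all(axis=0)].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    ref = counts.loc[housekeeping] if housekeeping is not None else counts
    with np.errstate(divide="ignore"):
        logref = np.log(ref.where(ref > 0))
    geomean = np.exp(logref.mean(axis=0, skipna=True))
    scaled = counts.div(geomean, axis=1)
    return np.log2(scaled + 1.0)


def differential_expression(matrix: pd.DataFrame, meta: pd.DataFrame,
                            group_a: str, group_b: str, p_cut: float = 0.05,
                            lfc_cut: float | None = None,
                            region: str | None = None) -> pd.DataFrame:
    """Per-transcript Welch t-test of group_a vs group_b on log2 values.

    log2FC = mean(group_a) - mean(group_b); the significance flag requires
    p < p_cut and, when ``lfc_cut`` is given, |log2FC| >= |lfc_cut|.
    """
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    if region is not None:
        m = m[m["region"] == region]
    cols_a = m.index[m["group"] == group_a]
    cols_b = m.index[m["group"] == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"need >= 2 samples per group "
                         f"({group_a}: {len(cols_a)}, {group_b}: {len(cols_b)})")
    A = matrix[cols_a].to_numpy(dtype=float)
    B = matrix[cols_b].to_numpy(dtype=float)
    lfc = A.mean(axis=1) - B.mean(axis=1)
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    sig = p < p_cut
    if lfc_cut is not None:
        sig = sig & (np.abs(lfc) >= abs(lfc_cut))
    return pd.DataFrame({"log2fc": lfc, "t": t, "p": p, "significant": sig,
                         "direction": np.where(lfc > 0, "up", "down")},
                        index=matrix.index)


@dataclass
class PCModel:
    loadings: pd.DataFrame        # transcripts x PCs
    contributions: pd.DataFrame   # transcripts x PCs, percent
    explained_variance_ratio: np.ndarray
    k_selected: int
    scores: pd.DataFrame          # samples x PCs


def pca_select(matrix: pd.DataFrame, variance_target: float = 0.95) -> PCModel:
    """PCA on transcript-centered samples; select the smallest component count
    whose cumulative explained variance reaches the target."""
    X = matrix.T.to_numpy(dtype=float)  # samples x transcripts
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples for PCA")
    pca = PCA()
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), variance_target) + 1)
    k = min(k, len(ratios))
    names = [f"PC{i + 1}" for i in range(len(ratios))]
    loadings = pd.DataFrame(pca.components_.T, index=matrix.index,
                            columns=names)
    contributions = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PCModel(loadings=loadings, contributions=contributions,
                   explained_variance_ratio=ratios, k_selected=k,
                   scores=pd.DataFrame(scores, index=matrix.columns,
                                       columns=names))


def top_contributors(model: PCModel, pc: int, k: int = 25) -> pd.DataFrame:
    """Top-k transcripts of a PC (1-based) by percent contribution."""
    name = f"PC{pc}"
    if name not in model.contributions.columns:
        raise ValueError(f"PC{pc} not fitted")
    out = pd.DataFrame({"contribution": model.contributions[name],
                        "loading": model.loadings[name]})
    out = out.sort_values("contribution", ascending=False)
    return out.head(min(k, len(out))).rename_axis("transcript").reset_index()


def venn_partition(sets: dict) -> pd.DataFrame:
    """Assign every member to its exclusive Venn region.

    Returns one row per element with a boolean column per set and a ``region``
    label like "A&B" naming exactly the sets containing it.
    """
    names = list(sets)
    universe = set().union(*sets.values()) if sets else set()
    rows = []
    for el in sorted(universe):
        membership = {name: el in sets[name] for name in names}
        region = "&".join(n for n in names if membership[n])
        rows.append({"element": el, **membership, "region": region})
    return pd.DataFrame(rows)


def combo_normalized_transcripts(deg_ogd_vs_control: pd.DataFrame,
                                 deg_az: pd.DataFrame,
                                 deg_epo: pd.DataFrame,
                                 deg_azepo: pd.DataFrame,
                                 definition: str = "not_significant") -> list:
    """Transcripts dysregulated by injury and normalized by the combination
    but not by either drug individually.

    All four DEG tables are treatment-vs-control comparisons on the same
    panel.  Under ``definition="not_significant"`` (default) a treatment
    normalizes a transcript when its treatment-vs-control comparison is no
    longer significant; ``definition="shifted_back"`` instead requires the
    treatment's |log2FC vs control| to drop below half the injury |log2FC|.
    """
    tables = {"ogd": deg_ogd_vs_control, "az": deg_az, "epo": deg_epo,
              "azepo": deg_azepo}
    panels = [tuple(t.index) for t in tables.values()]
    if len(set(panels)) != 1:
        raise ValueError("DEG tables are on mismatched panels")
    if definition == "not_significant":
        normalized = {k: ~t["significant"] for k, t in tables.items()}
    elif definition == "shifted_back":
        half = 0.5 * deg_ogd_vs_control["log2fc"].abs()
        normalized = {k: t["log2fc"].abs() < half for k, t in tables.items()}
    else:
        raise ValueError(f"unknown definition {definition!r}")
    keep = (deg_ogd_vs_control["significant"]
            & normalized["azepo"] & ~normalized["az"] & ~normalized["epo"])
    return list(deg_ogd_vs_control.index[keep])


def read_gmt(path) -> dict:
    """Parse a GMT gene-set file: name, description, then member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def geneset_enrichment(query, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric enrichment with Benjamini-Hochberg adjustment.

    fold enrichment = (overlap/|query|) / (|set|/|universe|).
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            raise ValueError(f"gene set {name!r} empty within the universe")
        n = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        fold = (k / N) / (n / M)
        rows.append({"set": name, "set_size": n, "overlap": k, "p": p,
                     "fold_enrichment": fold})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("p").reset_index(drop=True)
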