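"""Per-triad, per-sample quantification of homoeolog expression bias.

A triad-sample is summarized two ways:

* its **ternary point** — the relative expression fractions (f_A, f_B, f_D)
  of the three homoeologs, a point on the 2-simplex;
* its **CV** — the coefficient of variation of the three homoeolog TPMs,
  a single scale-free dispersion measure (0 for balanced expression, sqrt(3)
  under the sample-SD convention when one homoeolog carries everything).

The 7-archetype categorical scheme (balanced, X-dominant, X-suppressed) is
kept for comparison: a point is assigned to the nearest archetype centroid in
Euclidean distance.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TriadTable

#: archetype centroids in (f_A, f_B, f_D); enum order is the tie-break order
CATEGORIES = (
    ("balanced", (1 / 3, 1 / 3, 1 / 3)),
    ("A_dominant", (1.0, 0.0, 0.0)),
    ("B_dominant", (0.0, 1.0, 0.0)),
    ("D_dominant", (0.0, 0.0, 1.0)),
    ("A_suppressed", (0.0, 0.5, 0.5)),
    ("B_suppressed", (0.5, 0.0, 0.5)),
    ("D_suppressed", (0.5, 0.5, 0.0)),
)


def ternary_coords(tpm_A: float, tpm_B: float, tpm_D: float):
    """Relative A/B/D fractions of one triad in one sample.

    Returns ``None`` (an undefined point) when the triad total is zero,
    rather than propagating NaN.
    """
    vals = np.asarray([tpm_A, tpm_B, tpm_D], dtype=float)
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative")
    total = vals.sum()
    if total == 0:
        return None
    return tuple(vals / total)


def triad_cv(tpm_A: float, tpm_B: float, tpm_D: float, ddof: int = 1):
    """Coefficient of variation of the three homoeolog TPMs.

    Scale-free: cv(k*x) = cv(x) for k > 0. With the sample-SD convention
    (ddof=1, the default) the range is [0, sqrt(3)]; with population SD
    (ddof=0) it is [0, sqrt(2)]. Returns ``None`` when the total is zero.
    """
    vals = np.asarray([tpm_A, tpm_B, tpm_D], dtype=float)
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative")
    mean = vals.mean()
    if mean == 0:
        return None
    return float(vals.std(ddof=ddof) / mean)


def classify_category(point, centroids=CATEGORIES) -> str:
    """Nearest-centroid archetype of a ternary point (first wins on ties)."""
    if point is None:
        raise ValueError("cannot classify an undefined ternary point")
    p = np.asarray(point, dtype=float)
    best, best_d = None, np.inf
    for name, c in centroids:
        d = float(np.sum((p - np.asarray(c)) ** 2))
        if d < best_d - 1e-15:
            best, best_d = name, d
    return best


def heb_table(tpm: ExpressionMatrix, tt: TriadTable, ddof: int = 1) -> pd.DataFrame:
    """Long table of HEB summaries: one row per (triad, sample).

    Columns: triad_id, sample, line, replicate, tpm_A/B/D, f_A/B/D, cv,
    category. Triads with zero total in a sample get NaN fractions/cv and
    category ``undefined``.
    """
    if tpm.units != "TPM":
        raise ValueError("heb_table expects TPM units")
    vals = tpm.values
    A = vals.reindex(tt.triads["gene_A"]).to_numpy()
    B = vals.reindex(tt.triads["gene_B"]).to_numpy()
    D = vals.reindex(tt.triads["gene_D"]).to_numpy()
    total = A + B + D
    with np.errstate(invalid="ignore", divide="ignore"):
        fA, fB, fD = A / total, B / total, D / total
        stacked = np.stack([A, B, D])
        cv = stacked.std(axis=0, ddof=ddof) / stacked.mean(axis=0)
    cents = np.array([c for _, c in CATEGORIES])
    names = np.array([n for n, _ in CATEGORIES], dtype=object)
    pts = np.stack([fA, fB, fD], axis=-1)  # triads x samples x 3
    d2 = ((pts[..., None, :] - cents[None, None, :, :]) ** 2).sum(axis=-1)
    cat = names[np.argmin(d2, axis=-1)]
    cat[total == 0] = "undefined"
    n_tri, n_samp = A.shape
    samples = tpm.values.columns
    out = pd.DataFrame({
        "triad_id": np.repeat(tt.triad_ids.to_numpy(), n_samp),
        "sample": np.tile(samples.to_numpy(), n_tri),
        "tpm_A": A.ravel(), "tpm_B": B.ravel(), "tpm_D": D.ravel(),
        "f_A": fA.ravel(), "f_B": fB.ravel(), "f_D": fD.ravel(),
        "cv": cv.ravel(), "category": cat.ravel(),
    })
    meta = tpm.samples[["line", "replicate"]]
    out = out.merge(meta, left_on="sample", right_index=True)
    mask = out["tpm_A"] + out["tpm_B"] + out["tpm_D"] == 0
    out.loc[mask, ["f_A", "f_B", "f_D", "cv"]] = np.nan
    return out


def filter_expressed_triads(tpm: ExpressionMatrix, tt: TriadTable,
                            min_tpm: float = 0.5,
                            lines: list[str] | None = None) -> pd.Index:
    """Triads expressed above threshold in every line.

    A triad passes for a line iff the mean over that line's replicates of the
    triad total (tpm_A + tpm_B + tpm_D) exceeds ``min_tpm`` and at least one
    homoeolog is nonzero; population-level retention requires passing in all
    ``lines`` (default: every line present, parents included).
    """
    if tpm.units != "TPM":
        raise ValueError("filter_expressed_triads expects TPM units")
    vals = tpm.values
    A = vals.reindex(tt.triads["gene_A"]).to_numpy()
    B = vals.reindex(tt.triads["gene_B"]).to_numpy()
    D = vals.reindex(tt.triads["gene_D"]).to_numpy()
    total = A + B + D
    any_nonzero = total > 0
    line_of = tpm.samples["line"]
    if lines is None:
        lines = list(line_of.unique())
    keep = np.ones(len(tt.triad_ids), dtype=bool)
    cols = {s: i for i, s in enumerate(vals.columns)}
    for line in lines:
        idx = [cols[s] for s in line_of.index[line_of == line]]
        mean_total = total[:, idx].mean(axis=1)
        keep &= (mean_total > min_tpm) & any_nonzero[:, idx].any(axis=1)
    return tt.triad_ids[keep]


def replicate_distance(points: np.ndarray, method: str = "mean_pairwise") -> float:
    """Between-replicate spread of ternary points (rows = replicates).

    ``mean_pairwise`` (default): mean Euclidean distance over replicate pairs.
    ``max_pairwise``: the largest pairwise distance.
    ``to_centroid``: mean distance to the replicate centroid.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        warnings.warn("single replicate: distance undefined, treated as 0",
                      stacklevel=2)
        return 0.0
    if method in ("mean_pairwise", "max_pairwise"):
        dists = [float(np.linalg.norm(a - b)) for a, b in combinations(pts, 2)]
        return max(dists) if method == "max_pairwise" else float(np.mean(dists))
    if method == "to_centroid":
        centroid = pts.mean(axis=0)
        return float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
    raise ValueError(f"unknown method {method!r}")


def filter_replicate_variability(heb: pd.DataFrame, max_distance: float = 0.01,
                                 method: str = "mean_pairwise") -> pd.Index:
    """Triads whose replicate ternary points stay within ``max_distance``.

    The spread statistic is computed per (triad, line); a triad is removed
    when any line exceeds the threshold. Returns the kept triad IDs.
    """
    wide = heb.pivot_table(index=["triad_id", "line"], columns="replicate",
                           values=["f_A", "f_B", "f_D"], aggfunc="first",
                           sort=False)
    reps = wide.columns.get_level_values(1).unique()
    pts = np.stack([wide.loc[:, (["f_A", "f_B", "f_D"], r)].to_numpy()
                    for r in reps], axis=1)  # (triad-line) x rep x 3
    diffs = pts[:, :, None, :] - pts[:, None, :, :]
    dist = np.sqrt((diffs**2).sum(axis=-1))  # pairwise replicate distances
    iu = np.triu_indices(len(reps), k=1)
    pairwise = dist[:, iu[0], iu[1]]
    with warnings.catch_warnings():  # all-NaN triad-lines count as stable
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "mean_pairwise":
            stat = np.nanmean(pairwise, axis=1)
        elif method == "max_pairwise":
            stat = np.nanmax(pairwise, axis=1)
        elif method == "to_centroid":
            centroid = np.nanmean(pts, axis=1, keepdims=True)
            stat = np.nanmean(np.linalg.norm(pts - centroid, axis=-1), axis=1)
        else:
            raise ValueError(f"unknown method {method!r}")
    stat = np.nan_to_num(stat, nan=0.0)
    exceeded = pd.Series(stat, index=wide.index).groupby("triad_id").max()
    all_ids = pd.Index(heb["triad_id"].unique(), name="triad_id")
    return all_ids[~all_ids.isin(exceeded.index[exceeded > max_distance])]


def replicate_category_consistency(heb: pd.DataFrame) -> pd.DataFrame:
    """Distinct HEB categories among replicates, per (triad, line).

    Returns a frame with n_categories in {1, 2, 3} per triad-line, ready for
    population summaries (% of lines whose replicates agree, split 2-ways or
    3-ways).
    """
    counts = (
        heb[heb["category"] != "undefined"]
        .groupby(["triad_id", "line"])["category"]
        .nunique()
        .rename("n_categories")
        .reset_index()
    )
    return counts


def consistency_summary(consistency: pd.DataFrame) -> pd.Series:
    """Percentage of triad-lines at each distinct-category count."""
    pct = consistency["n_categories"].value_counts(normalize=True) * 100
    return pct.reindex([1, 2, 3], fill_value=0.0).rename("percent")
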