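"""Interpretation of learned phenotypes, neighborhoods, and areas.

For each microenvironmental element the module extracts its most confident
patches, profiles marker expression (column-normalized heatmaps), marker
colocalization (per-patch Spearman, averaged), nucleus morphology (Otsu +
watershed segmentation of the DAPI channel), composition of the level below
(argmax counting over 2-hop neighborhoods, z-scored), and differential
abundance between patient classes (two-sided Mann-Whitney-Wilcoxon with
Bonferroni correction).  Covariate associations use Spearman correlation
for ordinal/continuous variables and two-sided t-tests for binary ones,
with Benjamini-Hochberg FDR across the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .graphs import PatchGraph, k_hop_nodes


# ---------------------------------------------------------------------------
# Top patches and marker profiles
# ---------------------------------------------------------------------------

def top_confidence_patches(S: np.ndarray, element: int, k: int = 100):
    """Indices and confidences of the k patches most assigned to ``element``.

    Sorted by descending confidence, ties broken by patch index.  If fewer
    than ``k`` patches exist, all are returned with a warning.
    """
    S = np.asarray(S)
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= element < S.shape[1]:
        raise IndexError(f"element {element} out of range ({S.shape[1]})")
    conf = S[:, element]
    if len(conf) < k:
        warnings.warn(f"only {len(conf)} patches available (k={k})")
        k = len(conf)
    # stable sort on negated confidence -> ties keep ascending patch index
    order = np.argsort(-conf, kind="stable")[:k]
    return order, conf[order]


def marker_intensity_heatmap(top_patch_tensors: list) -> np.ndarray:
    """``E x C`` mean marker intensity of each element's top patches,
    column-normalized so every marker's maximum over elements is one.

    ``top_patch_tensors[e]`` is a list of (p, p, C) arrays; an element with
    no patches yields a zero row (with a warning).
    """
    E = len(top_patch_tensors)
    C = None
    rows = []
    for e in range(E):
        tensors = top_patch_tensors[e]
        if len(tensors) == 0:
            warnings.warn(f"element {e} has no top patches; zero row")
            rows.append(None)
            continue
        C = tensors[0].shape[2]
        rows.append(np.mean([t.reshape(-1, C).mean(axis=0) for t in tensors],
                            axis=0))
    if C is None:
        raise ValueError("no element has any patch")
    M = np.stack([r if r is not None else np.zeros(C) for r in rows])
    colmax = M.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(colmax > 0, M / np.where(colmax > 0, colmax, 1.0), 0.0)
    return M


def _spearman_pair(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0  # constant-channel rule
    r = stats.spearmanr(a, b).statistic
    return 0.0 if np.isnan(r) else float(r)


def colocalization_matrix(patch_tensors: list) -> np.ndarray:
    """``C x C`` marker colocalization: per-patch Spearman between flattened
    channel pairs, averaged over patches; diagonal is 1."""
    if len(patch_tensors) == 0:
        raise ValueError("need at least one patch")
    C = patch_tensors[0].shape[2]
    acc = np.zeros((C, C))
    for t in patch_tensors:
        flat = t.reshape(-1, C)
        for i in range(C):
            for j in range(i + 1, C):
                r = _spearman_pair(flat[:, i], flat[:, j])
                acc[i, j] += r
                acc[j, i] += r
    acc /= len(patch_tensors)
    np.fill_diagonal(acc, 1.0)
    return acc


# ---------------------------------------------------------------------------
# Nucleus morphology (classical segmenter on DAPI)
# ---------------------------------------------------------------------------

def segment_nuclei(dapi: np.ndarray, min_distance: int = 3) -> np.ndarray:
    """Label nuclei in a single-channel image.

    Otsu threshold, hole filling, then a distance-transform watershed to
    split touching nuclei.  Deterministic; a blank image yields zero labels.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("expected a single-channel image")
    if dapi.max() <= 0 or np.ptp(dapi) == 0:
        return np.zeros(dapi.shape, dtype=int)
    thr = threshold_otsu(dapi)
    mask = dapi > thr
    if not mask.any():
        return np.zeros(dapi.shape, dtype=int)
    mask = ndimage.binary_fill_holes(mask)
    dist = ndimage.distance_transform_edt(mask)
    # seed markers: local maxima of the distance map, one per nucleus
    footprint = np.ones((2 * min_distance + 1, 2 * min_distance + 1))
    maxima = (dist == ndimage.maximum_filter(dist, footprint=footprint)) & mask
    markers, n = ndimage.label(maxima)
    if n == 0:
        markers, _ = ndimage.label(mask)
    labels = watershed(-dist, markers=markers, mask=mask)
    return labels.astype(int)


def morphology_features(mask: np.ndarray) -> tuple:
    """(mean nucleus area px^2, nuclei count, mean circularity).

    Circularity is ``4 pi A / perimeter^2`` clipped to [0, 1]; an empty mask
    yields zeros.
    """
    mask = np.asarray(mask)
    props = regionprops(mask)
    if not props:
        return 0.0, 0, 0.0
    areas, circs = [], []
    for p in props:
        areas.append(p.area)
        if p.perimeter > 0:
            circs.append(min(1.0, 4 * np.pi * p.area / p.perimeter ** 2))
        else:
            circs.append(1.0)  # single-pixel object
    return float(np.mean(areas)), len(props), float(np.mean(circs))


# ---------------------------------------------------------------------------
# Composition matrices
# ---------------------------------------------------------------------------

def _zscore_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    return (M - mu) / np.where(sd > 0, sd, 1.0)


def _colmax_one(M: np.ndarray) -> np.ndarray:
    cm = M.max(axis=0)
    return np.where(cm > 0, M / np.where(cm > 0, cm, 1.0), 0.0)


def neighborhood_composition(S_P: np.ndarray, S_N: np.ndarray,
                             graph: PatchGraph, k: int = 100,
                             hops: int = 2, scheme: str = "zscore"):
    """``N x P`` composition of each neighborhood's local phenotypes.

    For each neighborhood's top-k patches, the argmax phenotype labels of
    the patches within ``hops`` graph hops (the 12-patch neighborhood at
    hops=2, plus the patch itself) are counted.  Normalization: ``zscore``
    per neighborhood row, or ``colmax`` (column maxima one) for display.
    """
    S_P, S_N = np.asarray(S_P), np.asarray(S_N)
    N, P = S_N.shape[1], S_P.shape[1]
    phen = np.argmax(S_P, axis=1)
    counts = np.zeros((N, P))
    for nb in range(N):
        idx, _ = top_confidence_patches(S_N, nb, k=min(k, S_N.shape[0]))
        for i in idx:
            nodes = k_hop_nodes(graph, int(i), hops) | {int(i)}
            for node in nodes:
                counts[nb, phen[node]] += 1
    if scheme == "zscore":
        return _zscore_rows(counts)
    if scheme == "colmax":
        return _colmax_one(counts)
    if scheme == "counts":
        return counts
    raise ValueError(f"unknown scheme {scheme!r}")


def area_composition(S_N: np.ndarray, S_A_neigh: np.ndarray,
                     scheme: str = "zscore") -> np.ndarray:
    """``A x N`` composition of areas over neighborhoods.

    Each patch's argmax neighborhood is counted into that neighborhood's
    argmax area; rows are z-scored per area (or column-max-one / raw).
    """
    S_N, S_A_neigh = np.asarray(S_N), np.asarray(S_A_neigh)
    N, A = S_A_neigh.shape
    area_of_neigh = np.argmax(S_A_neigh, axis=1)
    neigh_counts = np.bincount(np.argmax(S_N, axis=1), minlength=N)
    counts = np.zeros((A, N))
    for nb in range(N):
        counts[area_of_neigh[nb], nb] = neigh_counts[nb]
    if scheme == "zscore":
        return _zscore_rows(counts)
    if scheme == "colmax":
        return _colmax_one(counts)
    if scheme == "counts":
        return counts
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Differential abundance and covariate associations
# ---------------------------------------------------------------------------

def differential_abundance(enrichments: pd.DataFrame,
                           labels: np.ndarray) -> pd.DataFrame:
    """Two-sided Mann-Whitney-Wilcoxon per element, Bonferroni-adjusted.

    ``enrichments``: patients x elements (normalized abundances).  Returns a
    DataFrame with U statistic, p, p_adj (= min(1, m p), m = element count),
    and the sign of the class difference.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be non-empty")
    g1 = enrichments.loc[labels == 1]
    g0 = enrichments.loc[labels == 0]
    m = enrichments.shape[1]
    rows = []
    for col in enrichments.columns:
        a, b = g1[col].to_numpy(), g0[col].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            u, p = len(a) * len(b) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="auto")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append({"element": col, "U": u, "p": p,
                     "p_adj": min(1.0, m * p),
                     "direction": np.sign(np.mean(a) - np.mean(b))})
    return pd.DataFrame(rows)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def covariate_association(enrichments: pd.DataFrame,
                          covariates: pd.DataFrame,
                          covariate_types: dict) -> pd.DataFrame:
    """Element-vs-covariate associations with BH FDR across the table.

    ``covariate_types[name]`` is ``"ordinal"`` (Spearman; also used for
    continuous variables such as age) or ``"binary"`` (two-sided t-test).
    Constant covariates produce an NA row with a warning.
    """
    rows = []
    cov = covariates.loc[enrichments.index]
    for cname in cov.columns:
        ctype = covariate_types.get(cname, "ordinal")
        x = cov[cname].to_numpy(dtype=float)
        for ename in enrichments.columns:
            y = enrichments[ename].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(f"covariate {cname} is constant; NA row")
                rows.append({"element": ename, "covariate": cname,
                             "statistic": np.nan, "p": np.nan})
                continue
            if ctype == "binary":
                a, b = y[x == x.max()], y[x == x.min()]
                t, p = stats.ttest_ind(a, b)
                rows.append({"element": ename, "covariate": cname,
                             "statistic": float(t), "p": float(p)})
            else:
                if np.ptp(y) == 0:
                    rows.append({"element": ename, "covariate": cname,
                                 "statistic": 0.0, "p": 1.0})
                    continue
                rho, p = stats.spearmanr(x, y)
                rows.append({"element": ename, "covariate": cname,
                             "statistic": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = benjamini_hochberg(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return out


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------

def render_assignment_overlay(core_pixels: np.ndarray, confidences: np.ndarray,
                              grid_shape: tuple, patch_size: int = 20,
                              alpha: float = 0.6, cmap: str = "cividis"
                              ) -> np.ndarray:
    """Confidence map over the tissue: per-patch scores upsampled to pixel
    blocks, run through a dark-to-yellow diverging-style colormap, and
    alpha-blended over the grayscale channel composite.  Output covers the
    patch-tiled region (``rows*patch_size x cols*patch_size x 3``)."""
    import matplotlib

    rows, cols = grid_shape
    confidences = np.asarray(confidences, dtype=float)
    if confidences.size != rows * cols:
        raise ValueError(
            f"confidence length {confidences.size} != grid {rows}x{cols}")
    conf_img = np.kron(confidences.reshape(rows, cols),
                       np.ones((patch_size, patch_size)))
    colormap = matplotlib.colormaps[cmap]
    rgb = colormap(np.clip(conf_img, 0, 1))[:, :, :3]
    h, w = rows * patch_size, cols * patch_size
    gray = core_pixels[:h, :w].mean(axis=2)
    gray = gray / max(gray.max(), 1e-9)
    base = np.repeat(gray[:, :, None], 3, axis=2)
    return (1 - alpha) * base + alpha * rgb


# ---------------------------------------------------------------------------
# Element profiles
# ---------------------------------------------------------------------------

@dataclass
class ElementProfile:
    """Everything known about one learned element."""

    kind: str                 # "P", "N", or "A"
    index: int
    top_patches: np.ndarray   # patch indices, descending confidence
    confidences: np.ndarray
    mean_intensity: np.ndarray        # C (column-normalized row)
    colocalization: np.ndarray        # C x C
    morphology: tuple                 # (area, density, circularity)
    composition: np.ndarray | None    # over the level below (None for P)
    abundance_stats: dict             # per-class mean normalized abundance
    p_adj: float


def profile_phenotypes(bundles: dict, patch_tensors: dict,
                       enrichments: pd.DataFrame, labels: np.ndarray,
                       dapi_index: int, k: int = 100) -> list:
    """Assemble an :class:`ElementProfile` per learned phenotype.

    ``bundles`` maps patient id to its assignment bundle and
    ``patch_tensors`` to the patient's list of (p, p, C) patch arrays in
    PatchSet row order.  Marker rows are column-normalized jointly, so each
    marker's maximum over phenotypes is one.
    """
    pids = list(bundles)
    P = bundles[pids[0]].S_P.shape[1]
    top_by_elem = {e: [] for e in range(P)}
    for pid in pids:
        S_P = bundles[pid].S_P
        tensors = patch_tensors[pid]
        for e in range(P):
            idx, conf = top_confidence_patches(S_P, e,
                                               k=min(k, S_P.shape[0]))
            top_by_elem[e].extend(
                (float(c), pid, int(i), tensors[i]) for i, c in
                zip(idx, conf))
    # keep the global top-k per element
    for e in range(P):
        top_by_elem[e].sort(key=lambda t: -t[0])
        top_by_elem[e] = top_by_elem[e][:k]
    heat = marker_intensity_heatmap(
        [[t[3] for t in top_by_elem[e]] for e in range(P)])
    da = differential_abundance(
        enrichments[[c for c in enrichments.columns
                     if c.startswith("P")]], labels)
    profiles = []
    for e in range(P):
        tensors = [t[3] for t in top_by_elem[e]]
        coloc = colocalization_matrix(tensors) if tensors else None
        if tensors:
            mosaic = np.concatenate([t[:, :, dapi_index] for t in
                                     tensors[:20]], axis=1)
            morph = morphology_features(segment_nuclei(mosaic))
        else:
            morph = (0.0, 0, 0.0)
        col = f"P{e + 1}"
        stats_row = da[da["element"] == col]
        grp = {int(cls): float(enrichments.loc[labels == cls, col].mean())
               for cls in np.unique(labels)}
        profiles.append(ElementProfile(
            kind="P", index=e,
            top_patches=np.array([t[2] for t in top_by_elem[e]]),
            confidences=np.array([t[0] for t in top_by_elem[e]]),
            mean_intensity=heat[e], colocalization=coloc,
            morphology=morph, composition=None, abundance_stats=grp,
            p_adj=float(stats_row["p_adj"].iloc[0])
            if not stats_row.empty else np.nan))
    return profiles
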