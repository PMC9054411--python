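"""Per-phase radiomic features: first-order, GLCM, GLRLM, GLZSM, morphology.

Each contrast phase of a case yields a fixed block of 43 named scalars:
12 first-order intensity statistics, 24 texture-matrix features averaged
over the four in-plane directions 0°/45°/90°/135°, and 7 morphological
descriptors of the VOI. Texture matrices are built per axial slice at the
given in-plane offset and accumulated over all slices before features are
evaluated (a 2.5D scheme matching the four stated angles); the zone-size
matrix is inherently direction-free and is replicated across the four
directions so its directional average is a no-op.

All entropies use log base 2. Gray levels enter feature formulas with
their 1-based values ``i = 1..G``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, spatial, stats

from .imaging_io import EmptyMaskError, PhaseVolume, QuantizedVOI, VOIMask, VOIStack, crop_to_bbox, quantize

# ---------------------------------------------------------------------------
# Fixed feature registry — output order is deterministic
# ---------------------------------------------------------------------------

FIRST_ORDER_NAMES = (
    "mean", "median", "minimum", "maximum", "range", "variance",
    "skewness", "kurtosis", "energy", "entropy", "uniformity",
    "mean_absolute_deviation",
)

GLCM_NAMES = (
    "glcm_energy", "glcm_contrast", "glcm_correlation", "glcm_entropy",
    "glcm_homogeneity", "glcm_dissimilarity", "glcm_sum_entropy",
    "glcm_cluster_shade", "glcm_cluster_prominence",
)

GLRLM_NAMES = (
    "glrlm_short_run_emphasis", "glrlm_long_run_emphasis",
    "glrlm_gray_level_nonuniformity", "glrlm_run_length_nonuniformity",
    "glrlm_run_percentage", "glrlm_low_gray_run_emphasis",
    "glrlm_high_gray_run_emphasis", "glrlm_short_run_low_gray_emphasis",
    "glrlm_short_run_high_gray_emphasis", "glrlm_long_run_low_gray_emphasis",
    "glrlm_long_run_high_gray_emphasis",
)

GLZSM_NAMES = (
    "glzsm_high_intensity_emphasis", "glzsm_high_intensity_large_area_emphasis",
    "glzsm_low_intensity_emphasis", "glzsm_low_intensity_large_area_emphasis",
)

TEXTURE_NAMES = GLCM_NAMES + GLRLM_NAMES + GLZSM_NAMES  # 9 + 11 + 4 = 24

MORPHOLOGY_NAMES = (
    "volume", "surface_area", "density", "maximum_diameter",
    "sphericity", "compactness", "surface_to_volume_ratio",
)

#: In-plane (row, col) unit offsets on an axial slice for each direction.
DIRECTIONS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}
DIRECTION_ORDER = (0, 45, 90, 135)


@dataclasses.dataclass(frozen=True)
class GLCMatrix:
    """Symmetric, sum-normalized gray-level co-occurrence matrix."""

    P: np.ndarray  # G x G, sums to 1 when any pair exists
    direction: int
    distance: int
    n_pairs: int  # ordered pair count before normalization


@dataclasses.dataclass(frozen=True)
class RunLengthMatrix:
    """Counts of maximal same-level runs: level (rows) x run length (cols)."""

    R: np.ndarray  # G x Lmax integer counts
    direction: int


@dataclasses.dataclass(frozen=True)
class ZoneSizeMatrix:
    """Counts of maximal 26-connected same-level zones: level x zone size."""

    Z: np.ndarray  # G x Smax integer counts


@dataclasses.dataclass(frozen=True)
class PhaseFeatureBlock:
    """The 43 named features of one phase: 12 + 24 + 7."""

    phase_id: str
    first_order: dict[str, float]
    texture: dict[str, float]
    morphology: dict[str, float]
    n_directional_evaluations: int

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        out.update(self.first_order)
        out.update(self.texture)
        out.update(self.morphology)
        return out


# ---------------------------------------------------------------------------
# First-order features
# ---------------------------------------------------------------------------

def first_order_features(q: QuantizedVOI, raw_intensities: np.ndarray) -> dict[str, float]:
    """12 first-order statistics of the in-mask intensity distribution.

    Moments use the population (biased) convention; skewness and excess
    kurtosis of a constant sample are defined as 0. energy, entropy and
    uniformity are computed on the normalized gray-level histogram of the
    quantized VOI, so a constant region gives energy 1, entropy 0,
    uniformity 1.
    """
    x = np.asarray(raw_intensities, dtype=float)
    if x.size == 0:
        raise EmptyMaskError("first-order features need a nonempty VOI")
    mu = float(x.mean())
    var = float(x.var())
    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    else:
        skew = 0.0
        kurt = 0.0
    lev = q.levels[q.mask]
    p = np.bincount(lev, minlength=q.G + 1)[1:].astype(float)
    p = p / p.sum()
    nz = p[p > 0]
    hist_energy = float(np.sum(p * p))
    hist_entropy = float(-np.sum(nz * np.log2(nz)))
    return {
        "mean": mu,
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": hist_energy,
        "entropy": hist_entropy,
        "uniformity": hist_energy,
        "mean_absolute_deviation": float(np.abs(x - mu).mean()),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm(q: QuantizedVOI, direction: int, distance: int = 1) -> GLCMatrix:
    """Co-occurrence matrix at one in-plane direction, pooled over slices.

    Pairs are counted in both orders (symmetric accumulation); only pairs
    with both voxels inside the mask contribute. With no valid pair the
    matrix is all-zero and downstream features take degenerate limits.
    """
    dr, dc = DIRECTIONS[direction]
    dr, dc = dr * distance, dc * distance
    G = q.G
    lev, m = crop_to_bbox(q.levels, q.mask, margin=0)
    counts = np.zeros(G * G, dtype=np.int64)
    nr, nc, ns = lev.shape
    # slice-wise shifted views; both orders added at the end via transpose
    r0, r1 = max(dr, 0), nr + min(dr, 0)
    c0, c1 = max(dc, 0), nc + min(dc, 0)
    if r1 > r0 and c1 > c0:
        a = lev[r0:r1, c0:c1, :]
        b = lev[r0 - dr:r1 - dr, c0 - dc:c1 - dc, :]
        valid = m[r0:r1, c0:c1, :] & m[r0 - dr:r1 - dr, c0 - dc:c1 - dc, :]
        if valid.any():
            flat = (a[valid] - 1) * G + (b[valid] - 1)
            counts += np.bincount(flat, minlength=G * G)
    C = counts.reshape(G, G)
    C = C + C.T  # symmetric: each pair in both orders
    total = int(C.sum())
    P = C / total if total > 0 else C.astype(float)
    return GLCMatrix(P=P, direction=direction, distance=distance, n_pairs=total)


def glcm_features(M: GLCMatrix) -> dict[str, float]:
    """Nine co-occurrence features; zero-variance correlation is 1 by convention."""
    P = M.P
    G = P.shape[0]
    if P.sum() == 0:  # degenerate: no valid pair in this direction
        return {
            "glcm_energy": 0.0, "glcm_contrast": 0.0, "glcm_correlation": 1.0,
            "glcm_entropy": 0.0, "glcm_homogeneity": 0.0, "glcm_dissimilarity": 0.0,
            "glcm_sum_entropy": 0.0, "glcm_cluster_shade": 0.0,
            "glcm_cluster_prominence": 0.0,
        }
    i = np.arange(1, G + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float(np.sum(i * px))
    sigma_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    # symmetric matrix: marginals coincide
    mu_y, sigma_y = mu_x, sigma_x
    diff = I - J
    if sigma_x > 0:
        corr = float((np.sum(I * J * P) - mu_x * mu_y) / (sigma_x * sigma_y))
    else:
        corr = 1.0
    nz = P[P > 0]
    # distribution of the diagonal sums i+j, k = 2..2G
    p_sum = np.zeros(2 * G + 1)
    np.add.at(p_sum, (I + J).astype(int).ravel(), P.ravel())
    ps_nz = p_sum[p_sum > 0]
    dev = I + J - mu_x - mu_y
    return {
        "glcm_energy": float(np.sum(P * P)),
        "glcm_contrast": float(np.sum(diff ** 2 * P)),
        "glcm_correlation": corr,
        "glcm_entropy": float(-np.sum(nz * np.log2(nz))),
        "glcm_homogeneity": float(np.sum(P / (1.0 + diff ** 2))),
        "glcm_dissimilarity": float(np.sum(np.abs(diff) * P)),
        "glcm_sum_entropy": float(-np.sum(ps_nz * np.log2(ps_nz))),
        "glcm_cluster_shade": float(np.sum(dev ** 3 * P)),
        "glcm_cluster_prominence": float(np.sum(dev ** 4 * P)),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _slice_lines(lev2: np.ndarray, m2: np.ndarray, direction: int):
    """Yield (levels, mask) 1D scan lines of one slice along a direction."""
    if direction == 0:  # along columns (offset (0,1)): lines are rows
        for r in range(lev2.shape[0]):
            yield lev2[r, :], m2[r, :]
    elif direction == 90:  # offset (1,0): lines are columns
        for c in range(lev2.shape[1]):
            yield lev2[:, c], m2[:, c]
    else:
        # 45: offset (1,1) -> main diagonals; 135: offset (1,-1) -> anti-diagonals
        a, m = (lev2, m2) if direction == 45 else (lev2[:, ::-1], m2[:, ::-1])
        nr, nc = a.shape
        for off in range(-(nr - 1), nc):
            yield np.diagonal(a, offset=off), np.diagonal(m, offset=off)


def _runs_in_line(lev: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of equal level within the masked parts of one line."""
    x = np.where(m, lev, 0)
    if x.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    change = np.nonzero(np.diff(x) != 0)[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [x.size - 1]))
    values = x[starts]
    lengths = ends - starts + 1
    keep = values > 0
    return values[keep], lengths[keep]


def glrlm(q: QuantizedVOI, direction: int) -> RunLengthMatrix:
    """Run-length matrix at one in-plane direction, pooled over slices."""
    G = q.G
    lev, m = crop_to_bbox(q.levels, q.mask, margin=0)
    max_len = max(lev.shape[0], lev.shape[1]) + 1
    R = np.zeros((G, max_len + 1), dtype=np.int64)
    for k in range(lev.shape[2]):
        for line_lev, line_m in _slice_lines(lev[:, :, k], m[:, :, k], direction):
            vals, lens = _runs_in_line(np.ascontiguousarray(line_lev),
                                       np.ascontiguousarray(line_m))
            if vals.size:
                np.add.at(R, (vals - 1, lens), 1)
    last = np.nonzero(R.any(axis=0))[0]
    R = R[:, : (last[-1] + 1)] if last.size else R[:, :2]
    return RunLengthMatrix(R=R, direction=direction)


def glrlm_features(M: RunLengthMatrix) -> dict[str, float]:
    R = M.R.astype(float)
    G, L = R.shape
    Nr = R.sum()
    if Nr == 0:
        return {name: 0.0 for name in GLRLM_NAMES}
    i = np.arange(1, G + 1, dtype=float)[:, None]
    l = np.arange(L, dtype=float)[None, :]
    l[0, 0] = 1.0  # column 0 is empty by construction; avoid 0/0
    n_vox = float(np.sum(R * np.arange(L)[None, :]))
    return {
        "glrlm_short_run_emphasis": float(np.sum(R / l ** 2) / Nr),
        "glrlm_long_run_emphasis": float(np.sum(R * l ** 2) / Nr),
        "glrlm_gray_level_nonuniformity": float(np.sum(R.sum(axis=1) ** 2) / Nr),
        "glrlm_run_length_nonuniformity": float(np.sum(R.sum(axis=0) ** 2) / Nr),
        "glrlm_run_percentage": float(Nr / n_vox),
        "glrlm_low_gray_run_emphasis": float(np.sum(R / i ** 2) / Nr),
        "glrlm_high_gray_run_emphasis": float(np.sum(R * i ** 2) / Nr),
        "glrlm_short_run_low_gray_emphasis": float(np.sum(R / (i ** 2 * l ** 2)) / Nr),
        "glrlm_short_run_high_gray_emphasis": float(np.sum(R * i ** 2 / l ** 2) / Nr),
        "glrlm_long_run_low_gray_emphasis": float(np.sum(R * l ** 2 / i ** 2) / Nr),
        "glrlm_long_run_high_gray_emphasis": float(np.sum(R * i ** 2 * l ** 2) / Nr),
    }


# ---------------------------------------------------------------------------
# GLZSM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glzsm(q: QuantizedVOI) -> ZoneSizeMatrix:
    """Zone-size matrix: maximal 3D 26-connected components of equal level."""
    lev, m = crop_to_bbox(q.levels, q.mask, margin=0)
    if not m.any():
        raise EmptyMaskError("zone-size matrix needs a nonempty VOI")
    G = q.G
    zone_sizes: dict[int, list[int]] = {}
    max_size = 1
    for g in np.unique(lev[m]):
        labeled, n = ndimage.label(lev == g, structure=_STRUCT_26)
        sizes = np.bincount(labeled.ravel())[1:]
        zone_sizes[int(g)] = sizes.tolist()
        if sizes.size:
            max_size = max(max_size, int(sizes.max()))
    Z = np.zeros((G, max_size + 1), dtype=np.int64)
    for g, sizes in zone_sizes.items():
        for s in sizes:
            Z[g - 1, s] += 1
    return ZoneSizeMatrix(Z=Z)


def glzsm_features(M: ZoneSizeMatrix) -> dict[str, float]:
    """High/low-intensity (large-area) zone emphases."""
    Z = M.Z.astype(float)
    G, S = Z.shape
    Nz = Z.sum()
    if Nz == 0:
        return {name: 0.0 for name in GLZSM_NAMES}
    i = np.arange(1, G + 1, dtype=float)[:, None]
    s = np.arange(S, dtype=float)[None, :]
    s[0, 0] = 1.0  # size-0 column is empty
    return {
        "glzsm_high_intensity_emphasis": float(np.sum(Z * i ** 2) / Nz),
        "glzsm_high_intensity_large_area_emphasis": float(np.sum(Z * i ** 2 * s ** 2) / Nz),
        "glzsm_low_intensity_emphasis": float(np.sum(Z / i ** 2) / Nz),
        "glzsm_low_intensity_large_area_emphasis": float(np.sum(Z * s ** 2 / i ** 2) / Nz),
    }


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def _surface_voxel_coords(mask: np.ndarray) -> np.ndarray:
    """Indices of mask voxels with at least one exposed face (6-neighborhood)."""
    interior = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1),
                                      border_value=0)
    return np.argwhere(mask & ~interior)


def morphology_features(
    mask: VOIMask, spacing: tuple[float, float, float], raw_intensities: np.ndarray
) -> dict[str, float]:
    """Seven shape/size descriptors of the VOI.

    volume = voxel count x voxel volume; surface area counts exposed voxel
    faces; maximum diameter is the largest pairwise distance (mm) between
    surface voxel centers; sphericity = pi^(1/3) (6V)^(2/3) / A;
    compactness = V / (sqrt(pi) A^(3/2)).
    """
    m = mask.mask
    n = int(m.sum())
    if n == 0:
        raise EmptyMaskError("morphology features need a nonempty VOI")
    sx, sy, sz = spacing
    voxel_volume = sx * sy * sz
    volume = n * voxel_volume
    face_areas = (sy * sz, sx * sz, sx * sy)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        padded = np.pad(m, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
        exposed = np.diff(padded.astype(np.int8), axis=axis) != 0
        area += fa * int(exposed.sum())
    pts = _surface_voxel_coords(m).astype(float) * np.asarray(spacing)
    if len(pts) == 1:
        max_diam = 0.0
    else:
        if len(pts) > 800:
            try:  # hull vertices suffice for the diameter
                pts = pts[spatial.ConvexHull(pts).vertices]
            except spatial.QhullError:
                pass
        max_diam = float(spatial.distance.pdist(pts).max())
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    return {
        "volume": float(volume),
        "surface_area": float(area),
        "density": float(np.mean(raw_intensities)),
        "maximum_diameter": max_diam,
        "sphericity": sphericity,
        "compactness": float(volume / (np.sqrt(np.pi) * area ** 1.5)),
        "surface_to_volume_ratio": float(area / volume),
    }


# ---------------------------------------------------------------------------
# Per-phase block
# ---------------------------------------------------------------------------

def texture_features_by_direction(q: QuantizedVOI, distance: int = 1) -> dict[int, dict[str, float]]:
    """All 24 texture features for each of the four directions (pre-average).

    The GLZSM block is direction-free; its four values are replicated so
    each direction carries a full set of 24 and the 24 x 4 = 96 directional
    evaluations average back to 24.
    """
    zf = glzsm_features(glzsm(q))
    out: dict[int, dict[str, float]] = {}
    for d in DIRECTION_ORDER:
        feats: dict[str, float] = {}
        feats.update(glcm_features(glcm(q, d, distance)))
        feats.update(glrlm_features(glrlm(q, d)))
        feats.update(zf)
        out[d] = feats
    return out


def phase_block(stack: VOIStack, phase_id: str, G: int = 64, distance: int = 1) -> PhaseFeatureBlock:
    """Compute the full 43-feature block for one phase of one case."""
    if phase_id not in stack.phases:
        raise KeyError(f"case {stack.case_id!r} has no phase {phase_id!r}")
    vol = stack.phases[phase_id]
    try:
        q = quantize(vol, stack.mask, G=G)
        raw = vol.voxels[stack.mask.mask]
        fo = first_order_features(q, raw)
        per_dir = texture_features_by_direction(q, distance)
        texture = {
            name: float(np.mean([per_dir[d][name] for d in DIRECTION_ORDER]))
            for name in TEXTURE_NAMES
        }
        morph = morphology_features(stack.mask, vol.spacing, raw)
    except Exception as exc:
        raise type(exc)(f"case {stack.case_id!r}, phase {phase_id!r}: {exc}") from exc
    return PhaseFeatureBlock(
        phase_id=phase_id,
        first_order=fo,
        texture=texture,
        morphology=morph,
        n_directional_evaluations=len(TEXTURE_NAMES) * len(DIRECTION_ORDER),
    )
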