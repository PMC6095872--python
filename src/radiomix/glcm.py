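"""Gray-level co-occurrence matrices and the 25 texture features.

A GLCM at offset d tabulates how often a voxel of level i neighbors a voxel
of level j at displacement d inside the tumor mask. In 3-D the 26-connected
neighborhood at distance 1 collapses, after identifying d with -d, to 13
unique direction representatives; one symmetric GLCM is built per direction
and each texture feature is reported as the mean over the 13 matrices.

All logarithms are base 2 and 0*log(0) is taken as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import DiscretizedImage, Mask3D

__all__ = [
    "GLCM_DIRECTIONS",
    "GLCMatrix",
    "glcm_matrix",
    "glcm_features",
    "GLCM_FEATURE_NAMES",
]


def _canonical_directions() -> tuple[tuple[int, int, int], ...]:
    """One representative per +/- pair of the 26-neighborhood at distance 1."""
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if d > tuple(-c for c in d):  # keep the lexicographically larger twin
                    dirs.append(d)
    return tuple(dirs)


GLCM_DIRECTIONS: tuple[tuple[int, int, int], ...] = _canonical_directions()
assert len(GLCM_DIRECTIONS) == 13

GLCM_FEATURE_NAMES = (
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_average",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_average_intensity",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity1",
    "glcm_homogeneity2",
    "glcm_idmn",
    "glcm_idn",
    "glcm_inverse_variance",
    "glcm_maximum_probability",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_sum_variance",
    "glcm_sum_of_squares",
    "glcm_imc1",
    "glcm_imc2",
)


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric co-occurrence probability matrix for one direction."""

    p: np.ndarray
    direction: tuple[int, int, int]
    distance: int = 1

    def __post_init__(self):
        p = np.asarray(self.p, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        if not np.allclose(p, p.T):
            raise ValueError("GLCM must be symmetric")
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("GLCM entries must be non-negative and sum to 1")
        object.__setattr__(self, "p", p)


def glcm_matrix(
    disc: DiscretizedImage,
    mask: Mask3D,
    direction: tuple[int, int, int],
    distance: int = 1,
) -> GLCMatrix | None:
    """Build the symmetric GLCM for one displacement, or None if no pairs.

    Ordered pairs (v, v + d*distance) with both endpoints inside the mask are
    counted; accumulating both (i,j) and (j,i) symmetrizes the matrix before
    normalization to unit sum.
    """
    if direction not in GLCM_DIRECTIONS:
        raise ValueError(f"direction {direction} is not a canonical representative")
    ng = disc.n_levels
    lv = disc.levels
    m = mask.voxels
    off = tuple(int(c) * int(distance) for c in direction)

    # slice views of the two pair endpoints
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, o in enumerate(off):
        n = lv.shape[ax]
        if abs(o) >= n:
            return None
        if o >= 0:
            src[ax] = slice(0, n - o)
            dst[ax] = slice(o, n)
        else:
            src[ax] = slice(-o, n)
            dst[ax] = slice(0, n + o)
    a = lv[tuple(src)]
    b = lv[tuple(dst)]
    valid = m[tuple(src)] & m[tuple(dst)]
    if not valid.any():
        return None
    ai = a[valid] - 1
    bi = b[valid] - 1
    counts = np.bincount(ai * ng + bi, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T
    p = counts / counts.sum()
    return GLCMatrix(p=p, direction=direction, distance=distance)


def _entropy2(q: np.ndarray) -> float:
    nz = q[q > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_scalar_features(g: GLCMatrix) -> dict[str, float]:
    """The 25 texture features of a single co-occurrence matrix."""
    p = g.p
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    kdiff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    sums = (ii + jj).astype(int)
    diffs = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, sums.ravel() - 2, p.ravel())
    np.add.at(p_diff, diffs.ravel(), p.ravel())

    idiff = np.abs(ii - jj)
    icent = ii + jj - mu_x - mu_y

    out: dict[str, float] = {}
    out["glcm_autocorrelation"] = float((ii * jj * p).sum())
    out["glcm_cluster_prominence"] = float((icent**4 * p).sum())
    out["glcm_cluster_shade"] = float((icent**3 * p).sum())
    out["glcm_cluster_tendency"] = float((icent**2 * p).sum())
    out["glcm_contrast"] = float((idiff**2 * p).sum())
    if sig_x > 0 and sig_y > 0:
        out["glcm_correlation"] = float(
            ((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y)
        )
    else:
        # a single-level region is perfectly (degenerately) correlated
        out["glcm_correlation"] = 1.0

    da = float((kdiff * p_diff).sum())
    out["glcm_difference_average"] = da
    out["glcm_difference_entropy"] = _entropy2(p_diff)
    out["glcm_difference_variance"] = float(((kdiff - da) ** 2 * p_diff).sum())
    out["glcm_average_intensity"] = mu_x
    out["glcm_dissimilarity"] = float((idiff * p).sum())
    out["glcm_energy"] = float((p**2).sum())
    ent = _entropy2(p)
    out["glcm_entropy"] = ent
    out["glcm_homogeneity1"] = float((p / (1.0 + idiff)).sum())
    out["glcm_homogeneity2"] = float((p / (1.0 + idiff**2)).sum())
    out["glcm_idmn"] = float((p / (1.0 + (idiff / ng) ** 2)).sum())
    out["glcm_idn"] = float((p / (1.0 + idiff / ng)).sum())
    offdiag = idiff > 0
    out["glcm_inverse_variance"] = float(
        (p[offdiag] / idiff[offdiag] ** 2).sum() if offdiag.any() else 0.0
    )
    out["glcm_maximum_probability"] = float(p.max())

    sa = float((ksum * p_sum).sum())
    se = _entropy2(p_sum)
    out["glcm_sum_average"] = sa
    out["glcm_sum_entropy"] = se
    # Haralick's original definition centers p_{x+y} on the sum entropy
    out["glcm_sum_variance"] = float(((ksum - se) ** 2 * p_sum).sum())
    out["glcm_sum_of_squares"] = float(((ii - mu_x) ** 2 * p).sum())

    # information measures of correlation
    hx = _entropy2(px)
    hy = _entropy2(py)
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxy).sum())
    hxy2 = float(-(pxy * log_pxy).sum())
    if hx == 0.0 and hy == 0.0:
        out["glcm_imc1"] = 0.0
        out["glcm_imc2"] = 0.0
    else:
        out["glcm_imc1"] = (ent - hxy1) / max(hx, hy)
        out["glcm_imc2"] = float(np.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - ent)))))
    return out


def glcm_features(
    disc: DiscretizedImage, mask: Mask3D, distance: int = 1
) -> dict[str, float]:
    """Direction-averaged texture features over the 13 canonical GLCMs.

    Directions yielding no valid voxel pair inside the mask are excluded from
    the average.
    """
    per_dir: list[dict[str, float]] = []
    for d in GLCM_DIRECTIONS:
        g = glcm_matrix(disc, mask, d, distance)
        if g is not None:
            per_dir.append(glcm_scalar_features(g))
    if not per_dir:
        raise ValueError("no GLCM direction produced a valid voxel pair")
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_FEATURE_NAMES
    }
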