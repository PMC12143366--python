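"""PCA of normalized expression and the evolution-vector angle analysis.

For each divergence level, an evolution vector runs from the centroid of the
ancestral samples to the centroid of the evolved samples in a plane spanned by
two principal components.  The acute angle between two such vectors, computed
from their slopes,

    angle = arctan( |m2 - m1| / |1 + m1*m2| ) * 180/pi ,

summarizes how parallel the transcriptome-wide responses of two divergence
levels are (0 deg = same direction modulo sense, 90 deg = perpendicular).  The
acute formula deliberately collapses sense (0 vs 180 deg); ``vector_angle``
offers the full dot-product angle when sense matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import NormalizedExpression
from .model import ExparallelError, SampleDesign


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components ("PC1", ...)
    loadings: pd.DataFrame  # genes x components
    variance_explained: np.ndarray  # fraction per component, non-increasing

    def plane_scores(self, plane: tuple[str, str]) -> pd.DataFrame:
        missing = [c for c in plane if c not in self.scores.columns]
        if missing:
            raise ExparallelError(f"components not in PCA result: {missing}")
        return self.scores[list(plane)]


def run_pca(norm: NormalizedExpression) -> PCAResult:
    """PCA with samples as observations and genes as variables, gene-wise
    centering, no scaling.  Deterministic sign convention: the largest-magnitude
    loading of each component is positive."""
    x = norm.logcpm.to_numpy(float).T  # samples x genes
    if x.shape[0] < 2:
        raise ExparallelError("PCA needs at least 2 samples")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s[0] <= 1e-12:
        raise ExparallelError("constant expression matrix; PCA undefined")
    rank = int((s > 1e-12 * s[0]).sum())
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    for k in range(rank):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    comps = [f"PC{k + 1}" for k in range(rank)]
    scores = pd.DataFrame(u * s, index=norm.sample_ids, columns=comps)
    loadings = pd.DataFrame(vt.T, index=norm.gene_ids, columns=comps)
    var = s ** 2 / (s ** 2).sum()
    return PCAResult(scores, loadings, var)


@dataclass
class EvolutionVector:
    """Centroid-to-centroid vector of one divergence level in a PC plane."""

    level: str
    plane: tuple[str, str]
    origin: tuple[float, float]  # mean ancestral score point
    tip: tuple[float, float]  # mean evolved score point
    slope: float | None  # None when the vector is vertical in the plane
    vertical: bool

    @property
    def delta(self) -> tuple[float, float]:
        return (self.tip[0] - self.origin[0], self.tip[1] - self.origin[1])


def evolution_vector(
    pca: PCAResult,
    design: SampleDesign,
    level: str,
    plane: tuple[str, str] = ("PC2", "PC3"),
) -> EvolutionVector:
    scores = pca.plane_scores(plane)
    present = set(scores.index)
    anc = [s for s in design.samples_at(level, "ancestral") if s in present]
    evo = [s for s in design.samples_at(level, "evolved") if s in present]
    if not anc or not evo:
        raise ExparallelError(f"level {level!r} lacks ancestral or evolved samples in the PCA")
    origin = scores.loc[anc].mean(axis=0).to_numpy()
    tip = scores.loc[evo].mean(axis=0).to_numpy()
    dx, dy = tip[0] - origin[0], tip[1] - origin[1]
    if dx == 0.0 and dy == 0.0:
        raise ExparallelError(f"degenerate evolution vector for level {level!r}")
    vertical = bool(abs(dx) < 1e-12 * max(1.0, abs(dy)))
    slope = None if vertical else float(dy / dx)
    return EvolutionVector(level, tuple(plane), (float(origin[0]), float(origin[1])),
                           (float(tip[0]), float(tip[1])), slope, vertical)


def angle_between(m1: float | None, m2: float | None) -> float:
    """Acute angle in degrees between two lines given by slopes (``None`` means
    vertical).  Perpendicular slopes give 90; two verticals give 0."""
    if m1 is None and m2 is None:
        return 0.0
    if m1 is None or m2 is None:
        m = m2 if m1 is None else m1
        return 90.0 - math.degrees(math.atan(abs(m)))
    # atan2 of (|dm|, |1 + m1 m2|) equals atan(|dm|/|1+m1 m2|) and handles the
    # perpendicular case 1 + m1 m2 = 0 exactly (-> 90 degrees)
    return math.degrees(math.atan2(abs(m2 - m1), abs(1.0 + m1 * m2)))


def vector_angle(v1: tuple[float, float], v2: tuple[float, float], acute: bool = False) -> float:
    """Dot-product angle in degrees between two plane vectors, in [0, 180]
    (or folded to [0, 90] with ``acute``)."""
    n1 = math.hypot(*v1)
    n2 = math.hypot(*v2)
    if n1 == 0 or n2 == 0:
        raise ExparallelError("zero-length vector has no direction")
    c = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1 * n2)
    ang = math.degrees(math.acos(max(-1.0, min(1.0, c))))
    if acute and ang > 90.0:
        ang = 180.0 - ang
    return ang


def level_angles(
    vectors: dict[str, EvolutionVector],
) -> list[dict]:
    """Pairwise acute slope angles (and full dot-product angles) between the
    evolution vectors of all divergence levels sharing one embedding/plane."""
    out = []
    levels = list(vectors)
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            va, vb = vectors[levels[i]], vectors[levels[j]]
            if va.plane != vb.plane:
                raise ExparallelError("angles only compare vectors in the same plane")
            out.append(
                {
                    "plane": "-".join(va.plane),
                    "level_a": va.level,
                    "level_b": vb.level,
                    "angle_deg": angle_between(va.slope, vb.slope),
                    "full_angle_deg": vector_angle(va.delta, vb.delta),
                }
            )
    return out
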