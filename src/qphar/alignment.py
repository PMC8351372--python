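"""Rigid pharmacophore-pharmacophore alignment.

Alignment searches for the proper rigid transform that superposes a query
pharmacophore onto a template so that as many type-compatible feature pairs
as possible overlap.  The search is seeded from feature triplets whose
pairwise-distance triangles approximately match (tolerance = the cluster
cutoff, 1.5 Å by default), each seed is superposed by least squares, the
correspondence is extended greedily with every additional pair that
overlaps under the current transform, and the transform is re-estimated.
The result maximising the overlap count (ties: lower RMSD) wins.

There is no randomness anywhere in the search; alignment is deterministic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Feature, Pharmacophore
from .perception import perceive_pharmacophore

_MAX_REFINE_ROUNDS = 5


@dataclass
class Correspondence:
    """Injective pairing of template-feature and query-feature indices."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        t_idx = [t for t, _ in self.pairs]
        q_idx = [q for _, q in self.pairs]
        if len(set(t_idx)) != len(t_idx) or len(set(q_idx)) != len(q_idx):
            raise ValueError("correspondence must be injective on both sides")
        if len(self.pairs) < 3:
            raise ValueError("correspondence needs at least 3 pairs")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AlignmentResult:
    rotation: np.ndarray          # 3x3, det +1
    translation: np.ndarray       # Å
    matched_pairs: Correspondence
    score: int                    # overlapping feature pairs after transform
    rmsd: float                   # Å over matched pairs
    aligned_query: Pharmacophore  # transformed copy of the query

    @property
    def sort_key(self):
        ci = self.aligned_query.conformer_index
        return (-self.score, self.rmsd, ci if ci is not None else 0)


def superpose(template_points: np.ndarray,
              query_points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rigid superposition (Kabsch).

    Returns (rotation, translation, rmsd) such that
    ``rotation @ q + translation`` minimises the RMSD to the template
    points over all proper rigid transforms.  Reflections are never
    returned.  Requires >= 3 points.
    """
    t = np.asarray(template_points, dtype=float)
    q = np.asarray(query_points, dtype=float)
    if t.shape != q.shape or t.ndim != 2 or t.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(t) < 3:
        raise ValueError("rigid superposition needs at least 3 points")
    t_cent = t.mean(axis=0)
    q_cent = q.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear sets: rotation not unique
        rot, _ = Rotation.align_vectors(t - t_cent, q - q_cent)
    R = rot.as_matrix()
    translation = t_cent - R @ q_cent
    # recompute the RMSD from the transformed points; scipy's residual loses
    # precision to cancellation near zero
    rmsd = float(np.sqrt(np.mean(np.sum((q @ R.T + translation - t) ** 2, axis=1))))
    return R, translation, rmsd


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    v1 = points[1] - points[0]
    v2 = points[2] - points[0]
    return float(np.linalg.norm(np.cross(v1, v2))) <= tol


def _greedy_extension(template: Pharmacophore, query: Pharmacophore,
                      R: np.ndarray, tvec: np.ndarray,
                      seed_pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """All additional overlapping pairs under the current transform,
    added nearest-first, injectively."""
    q_pos = query.positions() @ R.T + tvec
    t_pos = template.positions()
    used_t = {t for t, _ in seed_pairs}
    used_q = {q for _, q in seed_pairs}
    candidates = []
    for ti, tf in enumerate(template.features):
        if ti in used_t:
            continue
        for qi, qf in enumerate(query.features):
            if qi in used_q or qf.type != tf.type:
                continue
            d = float(np.linalg.norm(t_pos[ti] - q_pos[qi]))
            if d < min(tf.radius, qf.radius):
                candidates.append((d, ti, qi))
    pairs = list(seed_pairs)
    for d, ti, qi in sorted(candidates):
        if ti in used_t or qi in used_q:
            continue
        used_t.add(ti)
        used_q.add(qi)
        pairs.append((ti, qi))
    return pairs


def _evaluate(template: Pharmacophore, query: Pharmacophore,
              pairs: list[tuple[int, int]]) -> AlignmentResult:
    t_pos = template.positions()
    q_pos = query.positions()
    t_idx = [t for t, _ in pairs]
    q_idx = [q for _, q in pairs]
    R, tvec, rmsd = superpose(t_pos[t_idx], q_pos[q_idx])
    q_aligned = q_pos @ R.T + tvec
    score = 0
    for ti, qi in pairs:
        d = float(np.linalg.norm(t_pos[ti] - q_aligned[qi]))
        if d < min(template.features[ti].radius, query.features[qi].radius):
            score += 1
    return AlignmentResult(
        rotation=R,
        translation=tvec,
        matched_pairs=Correspondence(sorted(pairs)),
        score=score,
        rmsd=rmsd,
        aligned_query=query.transformed(R, tvec),
    )


def align_pharmacophores(query: Pharmacophore, template: Pharmacophore,
                         tolerance: float | None = None) -> AlignmentResult | None:
    """Best rigid alignment of ``query`` onto ``template``.

    ``tolerance`` (Å) bounds the pairwise-distance mismatch allowed when
    seeding correspondences from feature triplets.  The default is twice
    the largest feature radius: two features can each sit within one
    radius of their partners while their pairwise distances differ by up
    to the sum of the radii, so a smaller tolerance would discard valid
    correspondences.  Returns None when no correspondence with at least 3
    genuinely overlapping pairs exists — the signal that a sample is
    out-of-domain.
    """
    if tolerance is None:
        tolerance = 2.0 * max(f.radius for f in
                              template.features + query.features)
    t_pos = template.positions()
    q_pos = query.positions()
    # type-compatible candidate query features per template feature
    compat = [
        [qi for qi, qf in enumerate(query.features) if qf.type == tf.type]
        for tf in template.features
    ]
    t_dist = np.linalg.norm(t_pos[:, None] - t_pos[None, :], axis=-1)
    q_dist = np.linalg.norm(q_pos[:, None] - q_pos[None, :], axis=-1)

    best: AlignmentResult | None = None
    for t_trip in itertools.combinations(range(len(template.features)), 3):
        if _collinear(t_pos[list(t_trip)]):
            continue
        ta, tb, tc = t_trip
        for qa in compat[ta]:
            for qb in compat[tb]:
                if qb == qa:
                    continue
                if abs(t_dist[ta, tb] - q_dist[qa, qb]) >= tolerance:
                    continue
                for qc in compat[tc]:
                    if qc in (qa, qb):
                        continue
                    if (abs(t_dist[ta, tc] - q_dist[qa, qc]) >= tolerance
                            or abs(t_dist[tb, tc] - q_dist[qb, qc]) >= tolerance):
                        continue
                    if _collinear(q_pos[[qa, qb, qc]]):
                        continue
                    pairs = [(ta, qa), (tb, qb), (tc, qc)]
                    R, tvec, _ = superpose(t_pos[list(t_trip)], q_pos[[qa, qb, qc]])
                    for _ in range(_MAX_REFINE_ROUNDS):
                        extended = _greedy_extension(template, query, R, tvec, pairs)
                        result = _evaluate(template, query, extended)
                        R, tvec = result.rotation, result.translation
                        if extended == pairs:
                            break
                        pairs = extended
                    if result.score < 3:
                        # fewer than 3 genuinely overlapping pairs is not a
                        # credible correspondence
                        continue
                    if best is None or result.sort_key < best.sort_key:
                        best = result
    return best


def sample_pharmacophores(sample, radius: float = 1.5) -> list[Pharmacophore]:
    """All conformer pharmacophores of a sample (perceiving molecules)."""
    if sample.pharmacophores is not None:
        return sample.pharmacophores
    mol = sample.molecule
    out = []
    for conf in mol.GetConformers():
        p = perceive_pharmacophore(mol, conf_id=conf.GetId(),
                                   sample_id=sample.sample_id, radius=radius)
        p.activity = sample.activity
        out.append(p)
    return out


def align_sample(sample, template: Pharmacophore,
                 tolerance: float | None = None) -> AlignmentResult | None:
    """Best alignment of a multi-conformer sample against the template.

    Greedy best-conformer selection: every conformer is aligned and the
    result with the highest score (ties: lowest RMSD, then lowest conformer
    index) is returned.  None marks the sample out-of-domain.
    """
    best: AlignmentResult | None = None
    for k, pharm in enumerate(sample_pharmacophores(sample)):
        if pharm.conformer_index is None:
            pharm.conformer_index = k
        result = align_pharmacophores(pharm, template, tolerance=tolerance)
        if result is None:
            continue
        if best is None or result.sort_key < best.sort_key:
            best = result
    return best
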