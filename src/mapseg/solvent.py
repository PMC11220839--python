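"""Solvent-content estimation from segmentation probabilities.

The per-voxel solvent probabilities P_i of a segmented map give an expected
solvent content S_U = (1/N) sum_i P_i.  A second, independent estimate comes
from the Matthews-coefficient analysis, which proposes candidate solvent
contents S_Mj (one per possible monomer count in the asymmetric unit) with
probabilities P_M(S_Mj).  The two are combined in three cases:

* a high-probability Matthews candidate close to S_U exists -> use that
  candidate's value unchanged;
* a candidate is only loosely consistent -> use the centroid of the
  conflation (pointwise product) of P_M with an empirical distribution P_U;
* no candidate is consistent -> use S_U alone.

P_U is a bin-based distribution over *logit cutoffs*: for each training
dataset, the cutoff l_c on log(P_i / (1 - P_i)) that reproduces the known
true solvent content is recorded, and the histogram of cutoffs, normalized
to 1, becomes P_U.  Evaluating P_U at a candidate solvent content S goes
through the dataset's own probability grid: S maps to the cutoff achieving
it, and P_U is read off at that cutoff.

The estimate is computed once, from the map after initial phasing, and is
flagged final: re-estimating from later, model-biased maps is deliberately
not supported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .map_io import ProbabilityGrid

__all__ = [
    "MatthewsPrediction",
    "EmpiricalLogitDistribution",
    "SolventEstimate",
    "CombineConfig",
    "expected_solvent",
    "symmetrize_grid",
    "solvent_at_cutoff",
    "find_logit_cutoff",
    "build_empirical_pu",
    "pu_of_solvent",
    "pm_interpolate",
    "conflate_centroid",
    "combine_estimates",
    "matthews_candidates",
]

logger = logging.getLogger(__name__)

#: Avogadro's number x 1e-24, converting A^3 to cm^3/mol in the Matthews formula.
_NA_SCALE = 6.02214076e-1
#: Protein partial specific volume, cm^3/g (the usual 0.74 convention).
PARTIAL_SPECIFIC_VOLUME = 0.74

_LOGIT_CLIP = 1e-9


@dataclass
class MatthewsPrediction:
    """Candidate solvent contents with Matthews probabilities.

    ``solvent`` must be strictly increasing; ``prob`` entries are
    non-negative with at least one positive.
    """

    solvent: np.ndarray
    prob: np.ndarray

    def __post_init__(self) -> None:
        self.solvent = np.atleast_1d(np.asarray(self.solvent, dtype=float))
        self.prob = np.atleast_1d(np.asarray(self.prob, dtype=float))
        if len(self.solvent) == 0:
            raise ValueError("at least one Matthews candidate is required")
        if len(self.solvent) != len(self.prob):
            raise ValueError("solvent and prob lengths differ")
        if (np.diff(self.solvent) <= 0).any():
            raise ValueError("candidate solvent contents must be strictly increasing")
        if (self.solvent <= 0).any() or (self.solvent >= 1).any():
            raise ValueError("candidate solvent contents must lie in (0, 1)")
        if (self.prob < 0).any() or not (self.prob > 0).any():
            raise ValueError("probabilities must be non-negative with one positive")

    @property
    def j_max(self) -> int:
        """Index of the most probable candidate."""
        return int(np.argmax(self.prob))

    @classmethod
    def uniform(cls, solvent_contents: np.ndarray) -> "MatthewsPrediction":
        """Fallback with equal probability on every candidate."""
        s = np.sort(np.asarray(solvent_contents, dtype=float))
        return cls(s, np.full(len(s), 1.0 / len(s)))


@dataclass
class EmpiricalLogitDistribution:
    """Bin-based probability distribution over logit cutoffs, summing to 1."""

    edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.edges) != len(self.probs) + 1:
            raise ValueError("need len(edges) == len(probs) + 1")
        if (self.probs < 0).any():
            raise ValueError("bin probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("bin probabilities must sum to 1")

    def evaluate(self, logit: float) -> float:
        """Probability of the bin containing ``logit`` (clipped to the range)."""
        lo, hi = self.edges[0], self.edges[-1]
        x = min(max(logit, lo), np.nextafter(hi, lo))
        i = int(np.searchsorted(self.edges, x, side="right")) - 1
        return float(self.probs[min(max(i, 0), len(self.probs) - 1)])

    def to_json(self) -> dict:
        return {"edges": self.edges.tolist(), "probs": self.probs.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "EmpiricalLogitDistribution":
        return cls(np.array(obj["edges"]), np.array(obj["probs"]))

    @classmethod
    def uniform(cls, lo: float = -8.0, hi: float = 8.0, bins: int = 50
                ) -> "EmpiricalLogitDistribution":
        return cls(np.linspace(lo, hi, bins + 1), np.full(bins, 1.0 / bins))


@dataclass
class SolventEstimate:
    """Final solvent-content estimate and the combination case that produced it."""

    value: float
    method: str  # matthews | conflation-centroid | segmentation-expectation
    segmentation_expectation: float
    matthews_value: float | None = None
    final: bool = True  # fixed after the initial cycle
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CombineConfig:
    """Thresholds of the three-case combination (all auditable in reports).

    ``p_high_fraction`` defines "high probability" relative to the largest
    candidate probability; ``delta_tight``/``delta_loose`` are absolute
    solvent-content windows around the segmentation expectation.
    """

    delta_tight: float = 0.05
    delta_loose: float = 0.15
    p_high_fraction: float = 0.5
    centroid_step: float = 0.001
    centroid_mode: str = "mean"  # or "mode" of the conflated product


def symmetrize_grid(grid: ProbabilityGrid) -> np.ndarray:
    """Average the grid over its symmetry operators.

    Operators are applied on voxel indices, which requires the rotation and
    translation to map the grid onto itself exactly (true for grids sampled
    compatibly with the space group).
    """
    ops = grid.symmetry_ops
    if len(ops) <= 1:
        return np.asarray(grid.values, dtype=float)
    n = np.array(grid.dims)
    idx = np.indices(grid.dims).reshape(3, -1)
    acc = np.zeros(grid.n_voxels)
    flat = np.asarray(grid.values, dtype=float).ravel()
    for rot, tran in ops:
        tn = tran * n
        if not (np.allclose(np.round(tn), tn, atol=1e-6)
                and np.allclose(rot, np.round(rot))):
            raise ValueError("symmetry operator does not map the grid onto itself")
        new = (np.round(rot).astype(int) @ idx + np.round(tn).astype(int)[:, None])
        new %= n[:, None]
        acc += flat[(new[0] * n[1] + new[1]) * n[2] + new[2]]
    return (acc / len(ops)).reshape(grid.dims)


def expected_solvent(grid: ProbabilityGrid) -> float:
    """Expected solvent content: the mean of P_i over the unit-cell grid.

    With symmetry operators present the mean is taken over the symmetrized
    grid, which equals the mean over a symmetry-reduced (asymmetric-unit)
    point set; for P1 both reduce to the plain full-cell mean.
    """
    if len(grid.symmetry_ops) > 1:
        return float(symmetrize_grid(grid).mean())
    return float(np.asarray(grid.values, dtype=float).mean())


def _logits(grid: ProbabilityGrid) -> np.ndarray:
    p = np.clip(np.asarray(grid.values, dtype=float).ravel(), _LOGIT_CLIP, 1 - _LOGIT_CLIP)
    return np.log(p / (1.0 - p))


def solvent_at_cutoff(grid: ProbabilityGrid, cutoff: float) -> float:
    """Fraction of voxels classified solvent at a logit cutoff.

    A voxel is solvent when logit(P_i) > cutoff; the result is non-increasing
    in the cutoff.
    """
    lg = _logits(grid)
    return float(np.count_nonzero(lg > cutoff) / lg.size)


def find_logit_cutoff(grid: ProbabilityGrid, true_solvent: float) -> float:
    """Logit cutoff whose classification reproduces ``true_solvent``.

    Chooses the cutoff (midpoint between adjacent sorted logits) whose
    achieved solvent fraction is the closest reachable to the target, i.e.
    within one voxel quantum 1/N.  For a degenerate grid where all P_i are
    equal, the target is unreachable except at 0 or 1 and the boundary
    cutoff is returned with a warning.
    """
    if not 0.0 <= true_solvent <= 1.0:
        raise ValueError("target solvent content must lie in [0, 1]")
    lg = np.sort(_logits(grid))[::-1]  # descending: first k voxels are solvent
    n = lg.size
    k = int(round(true_solvent * n))
    if k <= 0:
        return float(lg[0] + 1.0)
    if k >= n:
        return float(lg[-1] - 1.0)
    hi, lo = lg[k - 1], lg[k]  # want exactly k voxels strictly above the cutoff
    if hi == lo:
        # ties (or a fully degenerate grid): target count not exactly reachable
        if lg[0] == lg[-1]:
            warnings.warn("all probabilities equal; returning boundary logit cutoff")
            return float(lg[0])
        # fall back to the nearest achievable count at this logit value
        return float(lo)
    return float(0.5 * (hi + lo))


def build_empirical_pu(
    training_items: list[tuple[ProbabilityGrid, float]],
    bins: int = 50,
    logit_range: tuple[float, float] = (-8.0, 8.0),
) -> EmpiricalLogitDistribution:
    """Empirical distribution of true-solvent logit cutoffs over a training set.

    For every (probability grid, true solvent content) pair the cutoff l_c is
    determined, the cutoffs are histogrammed over ``logit_range`` (values
    outside the range land in the edge bins) and the histogram is normalized
    to sum to 1.
    """
    if not training_items:
        raise ValueError("need at least one training item")
    edges = np.linspace(logit_range[0], logit_range[1], bins + 1)
    cuts = np.array([find_logit_cutoff(g, s) for g, s in training_items])
    cuts = np.clip(cuts, edges[0], np.nextafter(edges[-1], edges[0]))
    counts, _ = np.histogram(cuts, bins=edges)
    return EmpiricalLogitDistribution(edges, counts / counts.sum())


def pu_of_solvent(grid: ProbabilityGrid, dist: EmpiricalLogitDistribution,
                  solvent: float) -> float:
    """P_U evaluated at a candidate solvent content.

    The candidate maps to the logit cutoff achieving it on this dataset's
    grid (a non-increasing map) and the distribution is read at that cutoff.
    """
    return dist.evaluate(find_logit_cutoff(grid, solvent))


def pm_interpolate(matthews: MatthewsPrediction, solvent: float | np.ndarray
                   ) -> float | np.ndarray:
    """Piecewise-linear Matthews density P_M on [0, 1].

    Linear interpolation through (0, 0), all (S_Mj, P_M(S_Mj)) and (1, 0);
    exact at the knots.
    """
    xs = np.concatenate(([0.0], matthews.solvent, [1.0]))
    ys = np.concatenate(([0.0], matthews.prob, [0.0]))
    out = np.interp(solvent, xs, ys)
    return float(out) if np.isscalar(solvent) else out


def conflate_centroid(
    grid: ProbabilityGrid,
    matthews: MatthewsPrediction,
    dist: EmpiricalLogitDistribution,
    step: float = 0.001,
    mode: str = "mean",
) -> float:
    """Solvent content at the centroid of the conflation of P_M and P_U.

    f(S) = P_M(S) * P_U(S) is evaluated on a uniform grid over (0, 1) at
    ``step`` and the centroid (first moment of the normalized product, or its
    mode when ``mode='mode'``) is returned via the trapezoid rule.  If the
    product vanishes everywhere the segmentation expectation is returned with
    a warning.
    """
    s = np.arange(step, 1.0, step)
    pm = pm_interpolate(matthews, s)
    sorted_lg = np.sort(_logits(grid))[::-1]
    n = sorted_lg.size
    # cutoff for each S without re-sorting: midpoint between adjacent order stats
    k = np.clip(np.round(s * n).astype(int), 0, n)
    cut = np.empty_like(s)
    for i, ki in enumerate(k):
        if ki <= 0:
            cut[i] = sorted_lg[0] + 1.0
        elif ki >= n:
            cut[i] = sorted_lg[-1] - 1.0
        else:
            cut[i] = 0.5 * (sorted_lg[ki - 1] + sorted_lg[ki])
    pu = np.array([dist.evaluate(c) for c in cut])
    f = pm * pu
    norm = np.trapezoid(f, s)
    if norm <= 0:
        warnings.warn("conflated distribution is identically zero; "
                      "falling back to the segmentation expectation")
        return expected_solvent(grid)
    if mode == "mode":
        return float(s[np.argmax(f)])
    return float(np.trapezoid(s * f, s) / norm)


def combine_estimates(
    grid: ProbabilityGrid,
    matthews: MatthewsPrediction | None,
    dist: EmpiricalLogitDistribution | None = None,
    config: CombineConfig | None = None,
) -> SolventEstimate:
    """Three-case combination of segmentation and Matthews estimates.

    1. consistent: a candidate with probability >= p_high lies within
       ``delta_tight`` of S_U -> that candidate's value, unchanged (ties go
       to the candidate nearest S_U, then to the higher probability);
    2. partial: some candidate lies within ``delta_loose`` -> the conflation
       centroid;
    3. inconsistent (or no candidates): S_U itself.

    The estimate is computed once from the initial-phasing map and flagged
    final; later density-modification cycles keep it fixed.
    """
    cfg = config or CombineConfig()
    s_u = expected_solvent(grid)
    audit = {"thresholds": asdict(cfg), "s_u": s_u}
    if matthews is None:
        return SolventEstimate(s_u, "segmentation-expectation", s_u, config=audit)
    p_high = cfg.p_high_fraction * float(matthews.prob.max())
    dev = np.abs(matthews.solvent - s_u)
    strong = (matthews.prob >= p_high) & (dev <= cfg.delta_tight)
    if strong.any():
        cand = np.flatnonzero(strong)
        # nearest to S_U, ties to higher probability
        order = sorted(cand, key=lambda j: (dev[j], -matthews.prob[j]))
        j = order[0]
        value = float(matthews.solvent[j])
        logger.info("solvent content: consistent Matthews candidate %.3f "
                    "(S_U = %.3f)", value, s_u)
        return SolventEstimate(value, "matthews", s_u, matthews_value=value,
                               config=audit)
    if (dev <= cfg.delta_loose).any():
        d = dist or EmpiricalLogitDistribution.uniform()
        value = conflate_centroid(grid, matthews, d, step=cfg.centroid_step,
                                  mode=cfg.centroid_mode)
        logger.info("solvent content: conflation centroid %.3f (S_U = %.3f)",
                    value, s_u)
        return SolventEstimate(value, "conflation-centroid", s_u,
                               matthews_value=float(matthews.solvent[matthews.j_max]),
                               config=audit)
    logger.info("solvent content: Matthews inconsistent, using S_U = %.3f", s_u)
    return SolventEstimate(s_u, "segmentation-expectation", s_u,
                           matthews_value=float(matthews.solvent[matthews.j_max]),
                           config=audit)


def matthews_candidates(
    cell_volume: float,
    n_symops: int,
    molecular_weight: float,
    max_monomers: int = 20,
    specific_volume: float = PARTIAL_SPECIFIC_VOLUME,
) -> np.ndarray:
    """Candidate solvent contents for 1..max_monomers per asymmetric unit.

    S_z = 1 - z * n_symops * MW * v / (V_cell * N_A * 1e-24) with the protein
    partial specific volume v = 0.74 cm^3/g by default.  Candidates outside
    (0, 1) are dropped; probabilities are left to the caller (see
    :meth:`MatthewsPrediction.uniform`).

    Parameters
    ----------
    cell_volume : float
        Unit-cell volume in cubic Angstrom.
    n_symops : int
        Number of symmetry operators (ASU copies per cell).
    molecular_weight : float
        Monomer molecular weight in Dalton.
    """
    if min(cell_volume, n_symops, molecular_weight, max_monomers) <= 0:
        raise ValueError("all inputs must be positive")
    z = np.arange(1, max_monomers + 1)
    protein_fraction = z * n_symops * molecular_weight * specific_volume / (
        cell_volume * _NA_SCALE)
    s = 1.0 - protein_fraction
    s = s[(s > 0) & (s < 1)]
    if len(s) == 0:
        raise ValueError(
            "no monomer count gives a solvent content in (0, 1); "
            "check the cell volume and molecular weight"
        )
    return np.sort(s)
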