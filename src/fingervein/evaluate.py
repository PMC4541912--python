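"""Verification-accuracy evaluation: pair enumeration, FAR/FRR/EER, d-prime.

Four class definitions ("experiment designs") assign every image a class:

* ``by_finger_hand_person`` — one class per physical finger (the usual
  biometric ground truth; person x hand x finger type);
* ``by_person`` — all six fingers of a person form one class;
* ``by_hand`` — two classes, left vs right hands of everybody;
* ``by_finger`` — three classes, index/middle/ring fingers of everybody.

Comparing the same database under the four designs isolates how much
discriminating information people, hands and finger types each carry.
Authentic tests compare two images of one class, imposter tests two images
of different classes; for a balanced database of M classes with N images
each the counts are A = C(N,2)·M and I = N²·C(M,2) (each unordered
cross-class pair counted once).

Scores are distances (smaller = more similar). Sweeping a threshold t gives
FAR(t) = %{imposter < t} and FRR(t) = %{authentic ≥ t}; the EER is read off
where the two curves cross. d-prime summarizes distribution separation as
(μ_I − μ_A) / sqrt((σ_A² + σ_I²)/2), positive when imposter distances exceed
authentic ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Callable, Hashable, Iterator

import numpy as np
from scipy import stats as sps

from .errors import ContractError, UnreliableDPrimeWarning
from .fusion import FusionRule, fuse_matrix
from .io import DatasetManifest, SampleLabel
from .veincode import pairwise_hamming

DEFAULT_N_THRESHOLDS = 10_001


@dataclass(frozen=True)
class ExperimentDesign:
    """A class-assignment rule over (person, hand, finger-type) labels."""

    name: str
    class_of: Callable[[SampleLabel], Hashable]


DESIGNS: dict[str, ExperimentDesign] = {
    "by_finger_hand_person": ExperimentDesign(
        "by_finger_hand_person", lambda lab: lab.finger_key
    ),
    "by_person": ExperimentDesign("by_person", lambda lab: lab.person_id),
    "by_hand": ExperimentDesign("by_hand", lambda lab: lab.hand),
    "by_finger": ExperimentDesign("by_finger", lambda lab: lab.finger_type),
}

#: CLI short names for the four class definitions.
DESIGN_ALIASES = {
    "fhp": "by_finger_hand_person",
    "person": "by_person",
    "hand": "by_hand",
    "finger": "by_finger",
}


@dataclass(frozen=True)
class PairCounts:
    """Closed-form matching-test counts for a balanced database."""

    M: int
    N: int
    authentic: int
    imposter: int


def pair_counts(M: int, N: int) -> PairCounts:
    """Counts for single-image matching: A = C(N,2)·M, I = N²·C(M,2)."""
    if M < 1 or N < 1:
        raise ContractError("M and N must be >= 1")
    return PairCounts(M, N, comb(N, 2) * M, N * N * comb(M, 2))


def enrollment_pair_counts(M: int, N: int, E: int) -> PairCounts:
    """Counts when every C(N,E) enrollment subset of a class is exercised.

    Each subset is matched against the N−E remaining images of its class
    (authentic) and against all N images of every other class (imposter):
    A = C(N,E)·(N−E)·M and I = C(N,E)·N·(M−1)·M.
    """
    if M < 1 or N < 1:
        raise ContractError("M and N must be >= 1")
    if not 1 <= E < N:
        raise ContractError(f"enrollment size E={E} must satisfy 1 <= E < N={N}")
    subsets = comb(N, E)
    return PairCounts(M, N, subsets * (N - E) * M, subsets * N * (M - 1) * M)


def enumerate_pairs(
    manifest: DatasetManifest, design: ExperimentDesign
) -> Iterator[tuple[int, int, bool]]:
    """Yield each unordered image pair once as (index_a, index_b, is_authentic).

    On a balanced manifest the authentic/imposter totals equal
    ``pair_counts``; unbalanced manifests are allowed with a warning.
    """
    labels = manifest.labels
    if not labels:
        raise ContractError("cannot enumerate pairs of an empty manifest")
    classes = [design.class_of(lab) for lab in labels]
    sizes: dict[Hashable, int] = {}
    for c in classes:
        sizes[c] = sizes.get(c, 0) + 1
    if len(set(sizes.values())) > 1:
        warnings.warn(
            f"manifest is unbalanced under design {design.name}: class sizes {sorted(set(sizes.values()))}",
            stacklevel=2,
        )
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            yield i, j, classes[i] == classes[j]


@dataclass
class ErrorRates:
    """FAR/FRR curves over a threshold grid, in percent, plus the EER."""

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray
    eer: float
    eer_threshold: float


@dataclass
class SeparationStats:
    """Means/standard deviations of the two score distributions and d-prime."""

    mu_authentic: float
    mu_imposter: float
    sigma_authentic: float
    sigma_imposter: float
    d_prime: float


@dataclass
class ScoreSet:
    """The raw authentic and imposter score samples of one experiment."""

    authentic: np.ndarray
    imposter: np.ndarray

    def histogram(self, bins: int = 100) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Shared-bin histograms (edges, authentic %, imposter %)."""
        lo = min(self.authentic.min(), self.imposter.min())
        hi = max(self.authentic.max(), self.imposter.max())
        edges = np.linspace(lo, hi, bins + 1)
        ha, _ = np.histogram(self.authentic, bins=edges)
        hi_, _ = np.histogram(self.imposter, bins=edges)
        return edges, 100.0 * ha / self.authentic.size, 100.0 * hi_ / self.imposter.size


def far_frr_curve(
    authentic, imposter, n_thresholds: int = DEFAULT_N_THRESHOLDS
) -> ErrorRates:
    """Sweep thresholds over the score range and locate the equal-error point.

    The grid is ``n_thresholds`` evenly spaced points spanning [min, max] of
    all scores. FAR(t) = %{imposter < t}, FRR(t) = %{authentic ≥ t}. The EER
    is (FAR+FRR)/2 at the grid point minimizing |FAR−FRR|; when the curves
    cross strictly between two grid points, both are linearly interpolated
    to the crossing.
    """
    auth = np.sort(np.asarray(authentic, dtype=np.float64).ravel())
    imp = np.sort(np.asarray(imposter, dtype=np.float64).ravel())
    if auth.size == 0 or imp.size == 0:
        raise ContractError("authentic and imposter score lists must be non-empty")
    if n_thresholds < 2:
        raise ContractError("need at least 2 threshold points")
    lo = min(auth[0], imp[0])
    hi = max(auth[-1], imp[-1])
    grid = np.linspace(lo, hi, n_thresholds)
    far = 100.0 * np.searchsorted(imp, grid, side="left") / imp.size
    frr = 100.0 * (auth.size - np.searchsorted(auth, grid, side="left")) / auth.size
    diff = far - frr
    i = int(np.argmin(np.abs(diff)))
    eer = 0.5 * (far[i] + frr[i])
    thr = float(grid[i])
    # refine by interpolation when the curves cross strictly between grid points
    for a, b in ((i, i + 1), (i - 1, i)):
        if 0 <= a and b < n_thresholds and diff[a] * diff[b] < 0:
            alpha = diff[a] / (diff[a] - diff[b])
            far_x = far[a] + alpha * (far[b] - far[a])
            frr_x = frr[a] + alpha * (frr[b] - frr[a])
            if abs(far_x - frr_x) < abs(diff[i]):
                eer = 0.5 * (far_x + frr_x)
                thr = float(grid[a] + alpha * (grid[b] - grid[a]))
            break
    return ErrorRates(grid, far, frr, float(eer), thr)


def d_prime(authentic, imposter) -> SeparationStats:
    """Standardized separation (μ_I − μ_A) / sqrt((σ_A² + σ_I²)/2).

    Uses population standard deviations. Positive for distance scores when
    imposters score higher; larger means better separation.
    """
    auth = np.asarray(authentic, dtype=np.float64).ravel()
    imp = np.asarray(imposter, dtype=np.float64).ravel()
    if auth.size < 2 or imp.size < 2:
        raise ContractError("d-prime needs at least 2 scores per distribution")
    mu_a, mu_i = float(auth.mean()), float(imp.mean())
    sd_a, sd_i = float(auth.std(ddof=0)), float(imp.std(ddof=0))
    denom = np.sqrt(0.5 * (sd_a**2 + sd_i**2))
    if denom == 0.0:
        if mu_a == mu_i:
            value = 0.0
        else:
            warnings.warn("degenerate zero-variance distributions; d-prime is infinite", stacklevel=2)
            value = float(np.inf) if mu_i > mu_a else float(-np.inf)
    else:
        value = (mu_i - mu_a) / denom
    return SeparationStats(mu_a, mu_i, sd_a, sd_i, float(value))


def screen_normality(scores, alpha: float = 0.01, label: str = "authentic") -> bool:
    """D'Agostino-Pearson normality screen; warns (and returns False) on failure.

    Used to flag d-prime values computed on visibly non-Gaussian score
    distributions — PRODUCT-rule fusion is the typical offender.
    """
    arr = np.asarray(scores, dtype=np.float64).ravel()
    if arr.size < 20 or arr.std() == 0:
        return True
    _, p = sps.normaltest(arr)
    if p < alpha:
        warnings.warn(
            f"{label} score distribution fails a normality screen (p={p:.2e}); "
            "its d-prime is an unreliable accuracy proxy",
            UnreliableDPrimeWarning,
            stacklevel=2,
        )
        return False
    return True


@dataclass
class ExperimentResult:
    """Everything one experiment produces: curves, separation stats, scores."""

    rates: ErrorRates
    stats: SeparationStats
    scores: ScoreSet
    n_authentic: int
    n_imposter: int


def evaluate_scores(
    authentic, imposter, n_thresholds: int = DEFAULT_N_THRESHOLDS
) -> ExperimentResult:
    auth = np.asarray(authentic, dtype=np.float64).ravel()
    imp = np.asarray(imposter, dtype=np.float64).ravel()
    return ExperimentResult(
        far_frr_curve(auth, imp, n_thresholds),
        d_prime(auth, imp),
        ScoreSet(auth, imp),
        auth.size,
        imp.size,
    )


def split_scores(
    labels: list[SampleLabel], distance_matrix: np.ndarray, design: ExperimentDesign
) -> ScoreSet:
    """Split an all-pairs distance matrix into authentic/imposter samples."""
    uniq: dict[Hashable, int] = {}
    codes = np.asarray([uniq.setdefault(design.class_of(lab), len(uniq)) for lab in labels])
    iu, ju = np.triu_indices(len(labels), k=1)
    same = codes[iu] == codes[ju]
    d = np.asarray(distance_matrix)[iu, ju]
    return ScoreSet(d[same], d[~same])


def evaluate_design(
    labels: list[SampleLabel],
    bits: np.ndarray,
    design: ExperimentDesign,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    distance_matrix: np.ndarray | None = None,
) -> ExperimentResult:
    """Run one class-definition experiment on pre-computed vein codes."""
    if distance_matrix is None:
        distance_matrix = pairwise_hamming(bits)
    scores = split_scores(labels, distance_matrix, design)
    return evaluate_scores(scores.authentic, scores.imposter, n_thresholds)


def run_experiment(
    manifest: DatasetManifest,
    design: ExperimentDesign,
    config=None,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
) -> ExperimentResult:
    """Code every manifest image once, then evaluate the given design."""
    from .pipeline import PipelineConfig, code_manifest

    config = config or PipelineConfig()
    _, bits = code_manifest(manifest, config)
    return evaluate_design(manifest.labels, bits, design, n_thresholds)


def _class_trial_order(labels: list[SampleLabel]) -> dict[Hashable, list[int]]:
    groups: dict[Hashable, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab.finger_key, []).append(i)
    for key, idx in groups.items():
        idx.sort(key=lambda i: labels[i].trial)
    return groups


def run_enrollment_experiment(
    labels: list[SampleLabel],
    subsampled: np.ndarray,
    bits: np.ndarray,
    n_enroll: int,
    max_shift: int = 5,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    enhance: bool = True,
    n_subsets: int = 1,
) -> ExperimentResult:
    """Multi-image enrollment under the per-finger class definition.

    For every finger class, ``n_subsets`` rotated enrollment subsets of
    ``n_enroll`` consecutive trials each form a shift-compensated average
    template; the class's remaining trials are authentic probes and every
    image of every other class is an imposter probe. Rotating subsets is a
    tractable stand-in for exercising all C(N, E) subsets and stabilizes the
    error-rate estimate at small database sizes.
    """
    from .enroll import average_enrollment
    from .veincode import hamming_to_set

    groups = _class_trial_order(labels)
    if any(len(idx) <= n_enroll for idx in groups.values()):
        raise ContractError("every class needs more than n_enroll images")
    if n_subsets < 1:
        raise ContractError("n_subsets must be >= 1")
    authentic, imposter = [], []
    for key, idx in groups.items():
        n = len(idx)
        others = [i for g, jdx in groups.items() if g != key for i in jdx]
        starts = sorted({(r * n) // n_subsets for r in range(n_subsets)})
        for start in starts:
            rotated = idx[start:] + idx[:start]
            enroll_idx, probe_idx = rotated[:n_enroll], rotated[n_enroll:]
            if n_enroll == 1:
                template_bits = bits[enroll_idx[0]]
            else:
                template = average_enrollment(
                    [subsampled[i] for i in enroll_idx], max_shift=max_shift, enhance=enhance
                )
                template_bits = template.code.bits
            authentic.append(hamming_to_set(template_bits, bits[probe_idx]))
            imposter.append(hamming_to_set(template_bits, bits[others]))
    return evaluate_scores(np.concatenate(authentic), np.concatenate(imposter), n_thresholds)


def run_fusion_experiment(
    labels: list[SampleLabel],
    bits: np.ndarray,
    n_inputs: int,
    rule: FusionRule | str,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    distance_matrix: np.ndarray | None = None,
) -> ExperimentResult:
    """Score-level fusion of ``n_inputs`` probe images per decision.

    The first ``n_inputs`` trials of every finger class act as the probe set.
    Each remaining image of the same class is an enrolled template yielding
    one fused authentic score; each image of every other class yields one
    fused imposter score. PRODUCT-rule authentic scores are screened for
    normality and a warning is issued when d-prime is unreliable.
    """
    rule = FusionRule(rule)
    if distance_matrix is None:
        distance_matrix = pairwise_hamming(bits)
    groups = _class_trial_order(labels)
    if any(len(idx) <= n_inputs for idx in groups.values()):
        raise ContractError("every class needs more than n_inputs images")
    authentic, imposter = [], []
    for key, idx in groups.items():
        probe_idx = idx[:n_inputs]
        enrolled_same = idx[n_inputs:]
        others = [i for g, jdx in groups.items() if g != key for i in jdx]
        authentic.append(fuse_matrix(distance_matrix[np.ix_(enrolled_same, probe_idx)], rule))
        imposter.append(fuse_matrix(distance_matrix[np.ix_(others, probe_idx)], rule))
    auth = np.concatenate(authentic)
    imp = np.concatenate(imposter)
    if rule is FusionRule.PRODUCT:
        screen_normality(auth, label=f"PRODUCT-fused ({n_inputs} scores) authentic")
    return evaluate_scores(auth, imp, n_thresholds)
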