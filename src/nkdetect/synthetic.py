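"""Synthetic NK-phenotype cohort generator.

Generates feature-by-patient tables with the marginal structure of the study
cohort this pipeline targets: 32 flow-cytometry percentage features with
group-conditional location/scale/range, marker+/marker- complement pairs that
sum to exactly 100, compositional CD16 blocks inside the CD56dim and
CD56bright gates, and a PSA value restricted to the diagnostically ambiguous
4.7-19 ng/ml window for the detection task.

Distribution parameters are transcribed from the published descriptive
statistics of the original 71-man cohort (30 benign, 41 cancer).  Two
marginal families are used: a truncated normal for roughly symmetric
features, and a bound-anchored shifted log-normal ("log-skewed") for features
whose dispersion is large relative to their distance from the nearer bound
(e.g. the LAIR-1 and DNAM-1 negative fractions).  Between-feature correlation
beyond the pair/block structure is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr, ndtri

from .cohort import Cohort
from .registry import COMPLEMENT_PAIRS

__all__ = [
    "GroupParams",
    "FeatureSpec",
    "PsaSpec",
    "SyntheticSpec",
    "GeneratorConfig",
    "GenerationError",
    "reference_spec",
    "default_risk_effect",
    "generate_detection_cohort",
    "generate_risk_cohort",
    "generate_planted_cohort",
]

#: Detection signature panel: GA-selected {2, 20, 27, 28} plus the
#: rank-test-selected {14, 15, 16, 17}.
SIGNATURE_PANEL = (2, 14, 15, 16, 17, 20, 27, 28)


class GenerationError(ValueError):
    """The requested spec cannot be sampled (e.g. bounds exclude the mean)."""


@dataclass(frozen=True)
class GroupParams:
    """Location/scale and hard bounds (percent, or ng/ml for PSA)."""

    location: float
    scale: float
    lower: float
    upper: float

    def interpolate(self, other: "GroupParams", alpha: float) -> "GroupParams":
        """Scale this group's departure from the two-group midpoint by
        ``alpha`` (0 pools the groups, 1 reproduces them).  The multiplier
        applies to the between-group location difference; scale and bounds
        are pooled for alpha < 1 but never extrapolated past the group's own
        values (extrapolated bounds can cross)."""

        def mix(a: float, b: float, w: float) -> float:
            mid = 0.5 * (a + b)
            return mid + w * (a - mid)

        beta = min(alpha, 1.0)
        return GroupParams(
            location=mix(self.location, other.location, alpha),
            scale=max(mix(self.scale, other.scale, beta), 1e-9),
            lower=mix(self.lower, other.lower, beta),
            upper=mix(self.upper, other.upper, beta),
        )


@dataclass(frozen=True)
class FeatureSpec:
    id: int
    family: str  # 'truncated-normal' | 'log-skewed'
    benign: GroupParams
    cancer: GroupParams
    complement_partner: int | None = None
    composition_block: str | None = None  # 'dim16' | 'bright16'

    def group(self, which: str) -> GroupParams:
        return self.benign if which == "benign" else self.cancer


@dataclass(frozen=True)
class PsaSpec:
    benign: GroupParams
    cancer: GroupParams
    family: str = "log-skewed"


@dataclass
class SyntheticSpec:
    features: dict[int, FeatureSpec]
    psa: PsaSpec
    pair_map: tuple[tuple[int, int], ...] = COMPLEMENT_PAIRS

    def feature(self, fid: int) -> FeatureSpec:
        return self.features[fid]


@dataclass
class GeneratorConfig:
    """Cohort shape and effect-size control for the detection generator.

    ``effect_scale`` multiplies the between-group difference of every
    distribution parameter: 0 pools the groups (an exact null), 1 reproduces
    the published group-conditional margins.
    """

    n_benign: int = 30
    n_cancer: int = 41
    seed: int = 0
    effect_scale: float = 1.0


# ---------------------------------------------------------------------------
# Reference parameters: per feature id ->
#   (benign (min, max, mean, std), cancer (min, max, mean, std))
# transcribed from the study's published per-group descriptive statistics.
_REFERENCE = {
    1: ((83.85, 96.61, 90.98, 3.35), (73.04, 96.98, 90.64, 5.46)),
    2: ((24.38, 87.46, 72.88, 11.74), (49.66, 89.33, 73.32, 10.22)),
    3: ((5.17, 64.22, 17.74, 10.40), (6.57, 44.00, 16.84, 7.45)),
    4: ((1.41, 11.11, 4.83, 2.45), (1.25, 18.06, 4.89, 3.48)),
    5: ((91.29, 98.70, 95.81, 2.02), (87.24, 98.70, 95.53, 2.58)),
    6: ((0.46, 5.10, 1.91, 1.06), (0.65, 5.88, 1.83, 1.04)),
    7: ((0.09, 1.97, 0.60, 0.44), (0.12, 1.15, 0.47, 0.25)),
    8: ((0.34, 3.11, 1.27, 0.72), (0.40, 4.95, 1.35, 0.86)),
    9: ((0.61, 5.78, 2.28, 1.14), (0.58, 9.09, 2.64, 1.82)),
    10: ((1.30, 8.71, 4.19, 2.02), (1.30, 12.76, 4.47, 2.58)),
    11: ((21.88, 86.70, 46.43, 15.64), (9.20, 80.47, 40.71, 14.66)),
    12: ((13.30, 78.12, 53.57, 15.64), (19.53, 90.80, 59.29, 14.66)),
    13: ((19.63, 82.38, 45.18, 15.31), (8.60, 77.47, 39.11, 14.10)),
    14: ((0.37, 4.75, 1.41, 1.07), (0.25, 6.64, 1.70, 1.41)),
    15: ((40.69, 96.74, 79.78, 16.42), (56.80, 98.43, 88.56, 10.41)),
    16: ((3.26, 58.34, 20.05, 16.22), (1.57, 44.59, 11.43, 10.46)),
    17: ((38.11, 86.52, 62.65, 13.49), (45.37, 95.82, 69.82, 11.58)),
    18: ((14.02, 62.97, 38.40, 13.58), (4.32, 55.68, 30.87, 11.64)),
    19: ((63.69, 99.18, 95.35, 6.81), (88.56, 99.60, 96.46, 2.59)),
    20: ((0.86, 37.29, 4.74, 6.96), (0.42, 11.66, 3.59, 2.61)),
    21: ((85.17, 98.77, 93.49, 4.45), (80.79, 98.96, 94.07, 4.87)),
    22: ((1.22, 14.76, 6.44, 4.36), (1.03, 19.12, 5.84, 4.76)),
    23: ((0.43, 3.71, 1.16, 0.82), (0.28, 6.77, 1.34, 1.20)),
    24: ((96.10, 99.53, 98.82, 0.83), (93.70, 99.70, 98.64, 1.13)),
    25: ((19.53, 84.73, 53.37, 19.04), (14.21, 91.59, 55.10, 18.34)),
    26: ((14.93, 81.54, 46.94, 19.21), (8.50, 86.08, 45.24, 18.43)),
    27: ((94.97, 99.90, 99.07, 1.07), (21.43, 99.89, 97.47, 12.19)),
    28: ((0.02, 5.24, 0.76, 1.02), (0.05, 78.20, 2.40, 12.15)),
    29: ((20.43, 77.57, 46.14, 17.41), (19.01, 73.01, 44.24, 13.73)),
    30: ((22.62, 79.40, 54.01, 17.39), (27.11, 80.85, 55.99, 13.67)),
    31: ((98.41, 99.99, 99.53, 0.39), (97.06, 99.96, 99.50, 0.59)),
    32: ((0.01, 1.59, 0.48, 0.39), (0.05, 2.95, 0.50, 0.59)),
}
_REFERENCE_PSA = ((4.70, 19.00, 8.26, 3.31), (4.70, 19.00, 8.34, 3.28))

_BLOCKS = {"dim16": (2, 3, 4), "bright16": (7, 8, 9)}
_PARTNER = {a: b for a, b in COMPLEMENT_PAIRS} | {b: a for a, b in COMPLEMENT_PAIRS}
#: Simulated member of each complement pair (the marker+ / total feature).
PAIR_PRIMARIES = tuple(a for a, _ in COMPLEMENT_PAIRS)


def _family_for(fid: int) -> str:
    """log-skewed when the printed std exceeds half the mean for either
    member of the feature's complement pair (either group)."""
    members = [fid] + ([_PARTNER[fid]] if fid in _PARTNER else [])
    for m in members:
        for lo, hi, mean, std in _REFERENCE[m]:
            if std > 0.5 * mean:
                return "log-skewed"
    return "truncated-normal"


def reference_spec() -> SyntheticSpec:
    """The packaged spec whose per-group means/stds/bounds equal the study
    cohort's published descriptive statistics."""
    features = {}
    for fid, (ben, can) in _REFERENCE.items():
        block = next((b for b, ids in _BLOCKS.items() if fid in ids), None)
        features[fid] = FeatureSpec(
            id=fid,
            family=_family_for(fid),
            benign=GroupParams(ben[2], ben[3], ben[0], ben[1]),
            cancer=GroupParams(can[2], can[3], can[0], can[1]),
            complement_partner=_PARTNER.get(fid),
            composition_block=block,
        )
    ben, can = _REFERENCE_PSA
    psa = PsaSpec(
        benign=GroupParams(ben[2], ben[3], ben[0], ben[1]),
        cancer=GroupParams(can[2], can[3], can[0], can[1]),
    )
    return SyntheticSpec(features=features, psa=psa)


# ---------------------------------------------------------------------------
# samplers

def _check_feasible(p: GroupParams, fid_label: str) -> None:
    if p.lower > p.upper:
        raise GenerationError(f"{fid_label}: lower bound exceeds upper bound")
    if p.scale <= 0:
        raise GenerationError(f"{fid_label}: scale must be positive")
    if p.location < p.lower - 6 * p.scale or p.location > p.upper + 6 * p.scale:
        raise GenerationError(
            f"{fid_label}: bounds [{p.lower}, {p.upper}] exclude the location "
            f"{p.location} by more than 6 scales"
        )


def _rtruncnorm(rng: np.random.Generator, p: GroupParams, size: int) -> np.ndarray:
    """Truncated normal via inverse-CDF (exact, vectorized)."""
    a = ndtr((p.lower - p.location) / p.scale)
    b = ndtr((p.upper - p.location) / p.scale)
    if b - a < 1e-12:  # degenerate truncation window
        return np.full(size, np.clip(p.location, p.lower, p.upper))
    u = rng.uniform(a, b, size=size)
    return p.location + p.scale * ndtri(u)


def _rlogskew(rng: np.random.Generator, p: GroupParams, size: int) -> np.ndarray:
    """Shifted log-normal anchored at the nearer bound, moment-matched to
    (location, scale) and clipped to the bounds."""
    loc = float(np.clip(p.location, p.lower, p.upper))
    right_skew = (loc - p.lower) <= (p.upper - loc)
    mean_z = (loc - p.lower) if right_skew else (p.upper - loc)
    if mean_z <= 1e-9:
        return np.full(size, loc)
    cv2 = (p.scale / mean_z) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(mean_z) - 0.5 * sigma**2
    z = np.clip(rng.lognormal(mu, sigma, size=size), 0.0, p.upper - p.lower)
    return p.lower + z if right_skew else p.upper - z


def _draw(rng: np.random.Generator, family: str, p: GroupParams, size: int,
          label: str = "feature") -> np.ndarray:
    _check_feasible(p, label)
    if family == "log-skewed":
        return _rlogskew(rng, p, size)
    return _rtruncnorm(rng, p, size)


def _rescale_block(v: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                   totals: np.ndarray) -> np.ndarray:
    """Rescale each row of ``v`` to sum to ``totals`` while (nearly always)
    keeping components inside their bounds; the last component absorbs any
    irreducible residual so that the compositional identity is exact."""
    v = v * (totals / v.sum(axis=1))[:, None]
    for _ in range(8):
        v = np.clip(v, lo, hi)
        resid = totals - v.sum(axis=1)
        if np.all(np.abs(resid) < 1e-9):
            break
        cap = np.where(resid[:, None] >= 0, hi - v, v - lo)
        capsum = np.maximum(cap.sum(axis=1), 1e-12)
        v = v + resid[:, None] * cap / capsum[:, None]
    resid = totals - v.sum(axis=1)
    v[:, -1] += resid  # exact identity trumps the last component's bound
    return v


def _shift(p: GroupParams, delta: float) -> GroupParams:
    return replace(p, location=p.location + delta) if delta else p


def _simulate_group(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    params: dict[int, GroupParams],
    psa_params: GroupParams,
    psa_family: str,
    size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one group's (size, 32) feature block and PSA vector.

    ``params`` maps every simulated feature id to its (possibly interpolated
    or shifted) group parameters.
    """
    X = np.empty((size, 32))

    def fam(fid: int) -> str:
        return spec.feature(fid).family

    # CD56dim/CD56bright split: simulate the dim total, derive the bright.
    p5 = params[5]
    p10 = params[10]
    p5 = replace(p5, lower=max(p5.lower, 100 - p10.upper),
                 upper=min(p5.upper, 100 - p10.lower))
    t = _draw(rng, fam(5), p5, size, "feature 5")
    X[:, 4] = t
    X[:, 9] = 100.0 - t

    # CD16 composition blocks, rescaled to their gate total.
    for block, (total_col, total_vec) in {
        "dim16": (0, t), "bright16": (5, 100.0 - t)
    }.items():
        ids = _BLOCKS[block]
        comps = np.column_stack(
            [_draw(rng, fam(i), params[i], size, f"feature {i}") for i in ids]
        )
        lo = np.array([params[i].lower for i in ids])
        hi = np.array([params[i].upper for i in ids])
        comps = _rescale_block(comps, lo, hi, total_vec)
        for k, i in enumerate(ids):
            X[:, i - 1] = comps[:, k]
        X[:, total_col] = comps[:, 0] + comps[:, 1]  # CD16+ = high + low

    # Independent features (no partner, no block).
    for fid in (13, 14):
        X[:, fid - 1] = _draw(rng, fam(fid), params[fid], size, f"feature {fid}")

    # Complement pairs: simulate the primary inside the intersection of its
    # own bounds and the complement of the partner's, derive the partner.
    for a, b in COMPLEMENT_PAIRS:
        if a == 5:
            continue
        pa, pb = params[a], params[b]
        pa = replace(pa, lower=max(pa.lower, 100 - pb.upper),
                     upper=min(pa.upper, 100 - pb.lower))
        x = _draw(rng, fam(a), pa, size, f"feature {a}")
        X[:, a - 1] = x
        X[:, b - 1] = 100.0 - x

    psa = _draw(rng, psa_family, psa_params, size, "PSA")
    return X, psa


def generate_detection_cohort(
    spec: SyntheticSpec, config: GeneratorConfig
) -> Cohort:
    """Simulate a benign-vs-cancer cohort (labels benign=0, cancer=1).

    Fully reproducible from ``config.seed``; complement pairs sum to exactly
    100 for every patient and PSA stays within the spec's window.
    """
    if config.n_benign <= 0 or config.n_cancer <= 0:
        raise ValueError("group counts must be positive")
    rng = np.random.default_rng(config.seed)
    alpha = config.effect_scale
    if not np.isfinite(alpha) or alpha < 0:
        raise ValueError("effect_scale must be finite and >= 0")

    blocks, psas, labels = [], [], []
    for gname, glabel, size in (
        ("benign", 0, config.n_benign), ("cancer", 1, config.n_cancer)
    ):
        params = {}
        for fid, fs in spec.features.items():
            other = fs.cancer if gname == "benign" else fs.benign
            params[fid] = fs.group(gname).interpolate(other, alpha)
        psa_other = spec.psa.cancer if gname == "benign" else spec.psa.benign
        psa_p = getattr(spec.psa, gname).interpolate(psa_other, alpha)
        X, psa = _simulate_group(rng, spec, params, psa_p, spec.psa.family, size)
        blocks.append(X)
        psas.append(psa)
        labels.append(np.full(size, glabel))

    n = config.n_benign + config.n_cancer
    return Cohort(
        values=np.vstack(blocks),
        psa=np.concatenate(psas),
        labels=np.concatenate(labels),
        patient_ids=[f"SYN{i:04d}" for i in range(n)],
        task="detection",
    )


def default_risk_effect(spec: SyntheticSpec, sd_mult: float = 1.5) -> dict[int, float]:
    """Packaged high-risk effect: a ``sd_mult`` pooled-std location shift on
    the eight signature-panel features, directed toward the bound with more
    room.  Complement-pair partners encode the same displacement as their
    primary, so the shift is attached to the simulated member of each pair.
    """
    shifts: dict[int, float] = {}
    done_pairs = set()
    for fid in SIGNATURE_PANEL:
        primary = fid
        if fid in _PARTNER and fid not in PAIR_PRIMARIES and fid != 5:
            primary = _PARTNER[fid]
        pair = tuple(sorted((primary, _PARTNER.get(primary, primary))))
        if pair in done_pairs:
            continue
        done_pairs.add(pair)
        p = spec.feature(primary).cancer
        pooled_sd = 0.5 * (spec.feature(primary).benign.scale + p.scale)
        sign = 1.0 if (p.upper - p.location) >= (p.location - p.lower) else -1.0
        shifts[primary] = sign * sd_mult * pooled_sd
    return shifts


def generate_risk_cohort(
    spec: SyntheticSpec,
    n_li: int = 38,
    n_h: int = 16,
    risk_effect: dict[int, float] | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate a cancer-only risk cohort (L/I=0, H=1).

    Both groups draw from the cancer-conditional margins; the high-risk group
    additionally shifts the ``risk_effect`` features and draws PSA from a
    heavy-tailed log-normal bounded by [4.3, 2617] ng/ml.
    """
    if n_li <= 0 or n_h <= 0:
        raise ValueError("group counts must be positive")
    rng = np.random.default_rng(seed)
    if risk_effect is None:
        risk_effect = default_risk_effect(spec)

    base = {fid: fs.cancer for fid, fs in spec.features.items()}

    X_li, psa_li = _simulate_group(
        rng, spec, base, spec.psa.cancer, spec.psa.family, n_li
    )

    shifted = {fid: _shift(p, risk_effect.get(fid, 0.0)) for fid, p in base.items()}
    # heavy-tailed H-group PSA: log-normal, median ~60 ng/ml, clipped
    h_psa_params = GroupParams(location=60.0, scale=1.4, lower=4.3, upper=2617.0)
    X_h, _ = _simulate_group(
        rng, spec, shifted, spec.psa.cancer, spec.psa.family, n_h
    )
    psa_h = np.clip(
        rng.lognormal(np.log(h_psa_params.location), h_psa_params.scale, n_h),
        h_psa_params.lower, h_psa_params.upper,
    )

    n = n_li + n_h
    return Cohort(
        values=np.vstack([X_li, X_h]),
        psa=np.concatenate([psa_li, psa_h]),
        labels=np.concatenate([np.zeros(n_li, int), np.ones(n_h, int)]),
        patient_ids=[f"RSK{i:04d}" for i in range(n)],
        task="risk",
    )


def generate_planted_cohort(
    n_benign: int = 150,
    n_cancer: int = 150,
    planted: tuple[int, ...] = (2, 20, 27, 28),
    shift_sds: float = 1.0,
    seed: int = 0,
    noise_sd: float = 10.0,
) -> Cohort:
    """Idealized cohort where exactly the ``planted`` features separate the
    groups (a ``shift_sds``-standard-deviation mean shift) and every other
    feature is pure noise.  Used for selection/classifier recovery checks.

    Defaults are sized so the plug-in mutual-information estimates
    concentrate: the planted set is then the population optimum of the mRMR
    difference criterion (at very strong shifts the label-induced pairwise
    dependence among signal features rivals their relevance and the
    criterion prefers to swap one out; at small n the MI estimates are too
    noisy to rank features stably)."""
    rng = np.random.default_rng(seed)
    n = n_benign + n_cancer
    X = rng.normal(50.0, noise_sd, size=(n, 32))
    labels = np.concatenate([np.zeros(n_benign, int), np.ones(n_cancer, int)])
    for fid in planted:
        X[labels == 1, fid - 1] += shift_sds * noise_sd
    X = np.clip(X, 0.0, 100.0)
    psa = np.clip(rng.normal(8.3, 3.3, size=n), 4.7, 18.99)
    return Cohort(
        values=X,
        psa=psa,
        labels=labels,
        patient_ids=[f"PLT{i:04d}" for i in range(n)],
        task="detection",
    )
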