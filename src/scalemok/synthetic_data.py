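"""Graded-response-model generator for Mokken-style questionnaire data.

Emulates a 9-item, five-level health-and-wellbeing questionnaire: a
dominant common factor realized as two correlated cluster factors (six
"psychosocial" and three "physical" items), additive known-group shifts of
the latent trait (long-term condition, carer), and decorative demographic
labels for stratified analyses.  Items follow the graded response
mechanism

    P(X_j >= x | theta) = logistic(D * a_j * (theta_f(j) - b_jx)),

with the conventional scaling constant D = 1.7 that puts the
discriminations a_j on the normal-ogive scale, so a_j = 1.8 is the strong
discrimination typical of well-scaling symptom items.  Responses are
sampled by one uniform draw per response against the cumulative system, so
a violation injected into the cumulative probabilities changes nothing
else about the stream: depth 0 reproduces the clean dataset bit for bit
under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import quad
from scipy.special import expit

from .data_model import GroupLabels, ResponseMatrix
from .errors import ConfigurationError

__all__ = ["GRMConfig", "ViolationSpec", "generate_grm", "inject_violation", "analytic_marginals"]

DEFAULT_ITEM_IDS = [
    "anxiety",
    "sad",
    "fatigue",
    "loneliness",
    "concentrating_thinking",
    "no_control",
    "pain",
    "daily_activities",
    "mobility",
]
# per-item overall difficulty; the minimum gap of 0.25 keeps conditional
# item means well separated, which gives the simulated instrument its
# (near) invariant item ordering; the overall level is set so item means
# fall in the 1.7-3.2 band typical of symptom questionnaires
DEFAULT_DIFFICULTY = [1.05, 0.8, 0.3, 1.3, 0.55, 1.55, 1.8, 2.05, 2.3]
DEFAULT_STEP_OFFSETS = [-1.8, -0.6, 0.6, 1.8]
DEFAULT_DISCRIMINATION = 1.8
SCALING_CONSTANT = 1.7  # logistic-to-normal-ogive scaling D


@dataclass
class GRMConfig:
    """Generator parameters; the defaults are the package's study conditions."""

    item_ids: list[str] = field(default_factory=lambda: list(DEFAULT_ITEM_IDS))
    levels: int = 5
    discriminations: np.ndarray | None = None  # default 1.8 for every item
    thresholds: np.ndarray | None = None  # J x (levels-1), strictly increasing
    cluster_assignment: np.ndarray | None = None  # default: 6 + 3 blocks
    factor_correlation: float = 0.5
    group_effects: dict[str, float] = field(
        default_factory=lambda: {"long_term_condition": 0.5, "carer": 0.3}
    )
    group_prevalences: dict[str, float] = field(
        default_factory=lambda: {"long_term_condition": 0.73, "carer": 0.27}
    )
    n: int = 3000
    seed: int | None = None
    scaling_constant: float = SCALING_CONSTANT  # set 1.0 for pure logistic

    def __post_init__(self) -> None:
        j = len(self.item_ids)
        m = self.levels - 1
        if self.discriminations is None:
            self.discriminations = np.full(j, DEFAULT_DISCRIMINATION)
        self.discriminations = np.asarray(self.discriminations, dtype=float)
        if np.any(self.discriminations <= 0):
            raise ConfigurationError("discriminations must be positive")
        if self.thresholds is None:
            base = np.asarray(DEFAULT_DIFFICULTY[:j] if j <= 9 else np.linspace(-1, 1, j))
            self.thresholds = base[:, None] + np.asarray(DEFAULT_STEP_OFFSETS[: m])[None, :]
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (j, m):
            raise ConfigurationError(f"thresholds must have shape {(j, m)}")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ConfigurationError("thresholds must be strictly increasing per item")
        if self.cluster_assignment is None:
            self.cluster_assignment = np.array([0] * min(6, j) + [1] * max(0, j - 6))
        self.cluster_assignment = np.asarray(self.cluster_assignment, dtype=int)
        if abs(self.factor_correlation) > 1:
            raise ConfigurationError("|factor_correlation| must be <= 1")
        for g, p in self.group_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence of {g!r} outside [0, 1]")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_factors(self) -> int:
        return int(self.cluster_assignment.max()) + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("discriminations", "thresholds", "cluster_assignment"):
            d[key] = np.asarray(d[key]).tolist()
        return d


@dataclass
class ViolationSpec:
    """A controlled departure from the GRM for adversarial fixtures.

    ``non_monotone``: one step's cumulative probability is lowered by
    `depth` inside the theta interval (later steps are clipped to keep the
    cumulative system valid), producing a dip in that ISRF.
    ``crossing``: every step is lowered by `depth` inside the interval
    (clipped at 0), so the item's IRF dives below items that are normally
    harder — an invariant-item-ordering violation.
    """

    target_item: str
    violation: str = "non_monotone"  # or "crossing"
    depth: float = 0.15
    theta_interval: tuple[float, float] = (0.0, np.inf)
    step: int | None = None  # 1-based ISRF index; default: middle step

    def __post_init__(self) -> None:
        if self.violation not in ("non_monotone", "crossing"):
            raise ConfigurationError(f"unknown violation type {self.violation!r}")
        if not 0.0 <= self.depth < 1.0:
            raise ConfigurationError("depth must lie in [0, 1)")
        lo, hi = self.theta_interval
        if not lo < hi:
            raise ConfigurationError("theta_interval must be well-ordered")


def _draw_latent(config: GRMConfig, rng: np.random.Generator):
    """Factor scores (n x n_factors) plus group membership labels."""
    n, nf = config.n, config.n_factors
    if nf == 1:
        theta = rng.standard_normal((n, 1))
    else:
        rho = config.factor_correlation
        cov = np.full((nf, nf), rho)
        np.fill_diagonal(cov, 1.0)
        theta = rng.multivariate_normal(np.zeros(nf), cov, size=n, method="cholesky")

    labels: dict[str, np.ndarray] = {}
    for g in sorted(config.group_effects):
        member = rng.random(n) < config.group_prevalences.get(g, 0.0)
        theta += np.where(member, config.group_effects[g], 0.0)[:, None]
        labels[g] = np.where(member, "yes", "no")

    # decorative strata with no latent effect, in the neighbourhood of the
    # target population (55% women; US/Australia/UK mix; four age bands)
    labels["gender"] = np.where(rng.random(n) < 0.55, "woman", "man")
    labels["country"] = rng.choice(
        ["US", "Australia", "UK"], size=n, p=[0.27, 0.15, 0.58]
    )
    labels["age_band"] = rng.choice(
        ["<=35", "36-50", "51-65", ">65"], size=n, p=[0.27, 0.23, 0.25, 0.25]
    )
    return theta, labels


def _cumulative_probs(config: GRMConfig, theta: np.ndarray) -> np.ndarray:
    """(n, J, m) array of P(X_j >= x | theta_i) for steps x = 1..m."""
    th_item = theta[:, config.cluster_assignment]  # n x J
    a = config.scaling_constant * config.discriminations[None, :, None]
    b = config.thresholds[None, :, :]
    return expit(a * (th_item[:, :, None] - b))


def _sample(config: GRMConfig, probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random((config.n, config.n_items))
    return (u[:, :, None] < probs).sum(axis=2)  # internal codes 0..m


def generate_grm(config: GRMConfig):
    """Sample a questionnaire dataset from the graded response model.

    Returns ``(matrix, group_labels, truth)`` where `truth` records the
    latent draws, group labels, cluster map and the full config echo, so
    recovery can be scored against generator ground truth.
    """
    rng = np.random.default_rng(config.seed)
    theta, labels = _draw_latent(config, rng)
    probs = _cumulative_probs(config, theta)
    internal = _sample(config, probs, rng)
    matrix = ResponseMatrix(
        internal,
        list(config.item_ids),
        np.zeros(internal.shape, dtype=bool),
        levels=config.levels,
    )
    truth = {
        "theta": theta,
        "theta_mean": theta.mean(axis=1),
        "labels": labels,
        "cluster_assignment": config.cluster_assignment.copy(),
        "violated_item": None,
        "config": config.to_dict(),
    }
    return matrix, GroupLabels(labels), truth


def inject_violation(config: GRMConfig, spec: ViolationSpec):
    """Generate data whose target item departs from the GRM as specified.

    Uses the same draw order as :func:`generate_grm`, so ``depth=0``
    reproduces the clean dataset exactly under the same seed.
    """
    jt = config.item_ids.index(spec.target_item) if spec.target_item in config.item_ids else None
    if jt is None:
        raise ConfigurationError(f"unknown target item {spec.target_item!r}")
    rng = np.random.default_rng(config.seed)
    theta, labels = _draw_latent(config, rng)
    probs = _cumulative_probs(config, theta)

    th_t = theta[:, config.cluster_assignment[jt]]
    lo, hi = spec.theta_interval
    in_interval = (th_t > lo) & (th_t < hi)
    m = config.levels - 1
    if spec.violation == "non_monotone":
        x = (spec.step if spec.step is not None else (m + 1) // 2) - 1
        if not 0 <= x < m:
            raise ConfigurationError(f"step must lie in 1..{m}")
        lowered = probs[in_interval, jt, x] - spec.depth
        if np.any(lowered < 0):
            raise ConfigurationError("depth drives a cumulative probability below 0")
        probs[in_interval, jt, x] = lowered
        # keep the cumulative system valid: later steps may not exceed it
        for later in range(x + 1, m):
            probs[in_interval, jt, later] = np.minimum(
                probs[in_interval, jt, later], lowered
            )
    else:  # crossing IRFs: whole curve lowered inside the interval
        probs[in_interval, jt, :] = np.clip(
            probs[in_interval, jt, :] - spec.depth, 0.0, 1.0
        )

    internal = _sample(config, probs, rng)
    matrix = ResponseMatrix(
        internal,
        list(config.item_ids),
        np.zeros(internal.shape, dtype=bool),
        levels=config.levels,
    )
    truth = {
        "theta": theta,
        "theta_mean": theta.mean(axis=1),
        "labels": labels,
        "cluster_assignment": config.cluster_assignment.copy(),
        "violated_item": spec.target_item,
        "violation": asdict(spec),
        "config": config.to_dict(),
    }
    return matrix, GroupLabels(labels), truth


def analytic_marginals(config: GRMConfig) -> np.ndarray:
    """Population level frequencies P(X_j = x) by numerical integration.

    Each item's latent trait is marginally a mixture of normals: N(0, 1)
    shifted by every on/off combination of the group effects, weighted by
    the prevalences.  Integration is over each mixture component.
    """
    shifts = np.array([0.0])
    weights = np.array([1.0])
    for g in sorted(config.group_effects):
        p = config.group_prevalences.get(g, 0.0)
        d = config.group_effects[g]
        shifts = np.concatenate([shifts, shifts + d])
        weights = np.concatenate([weights * (1.0 - p), weights * p])

    j, m = config.n_items, config.levels - 1
    out = np.zeros((j, config.levels))
    norm = 1.0 / np.sqrt(2 * np.pi)
    for jj in range(j):
        a = config.scaling_constant * config.discriminations[jj]
        b = config.thresholds[jj]
        cum = np.zeros(m)
        for x in range(m):
            val = 0.0
            for s, w in zip(shifts, weights):
                f = lambda t: expit(a * (t + s - b[x])) * norm * np.exp(-t * t / 2)
                val += w * quad(f, -9, 9, limit=200)[0]
            cum[x] = val
        full = np.concatenate([[1.0], cum, [0.0]])
        out[jj] = full[:-1] - full[1:]  # P(X = x) = P(>= x) - P(>= x+1)
    return out
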