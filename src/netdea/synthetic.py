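"""Synthetic hospital panels with the structural features the model assumes.

The generator emulates a national-health-service hospital panel: 27 units
observed over 4 yearly periods, 19 absolute-valued variables —

* capacity/labour/cost inputs  E1 (beds), E2/E3 (doctor/nurse hours),
  E4–E6 (operational / personnel / outsourcing costs),
* production volumes           E7 (inpatients), E8 (outpatient visits),
  E9 (surgeries),
* quality counts               Q1–Q3 desirable, Q4–Q7 undesirable events,
* access                       A1 desirable, A2 undesirable counts,
  A3 waiting days.

Structure: a latent scale drives everything multiplicatively with lognormal
noise (the variables are positive, heavy-tailed counts and costs, so
multiplicative noise keeps strict positivity without truncation artefacts);
staff hours track beds, costs track staff — reproducing the collinearity
that screening is meant to find, with requested pairs calibrated to a target
correlation; production volumes are divided by a per-DMU inefficiency factor
>= 1, so inefficiency is an input excess relative to output; event counts
are binomial draws bounded cellwise by their volume column (Q1, Q2, Q4,
Q5 <= E7; Q3, Q6, Q7, A1 <= E9; A2 <= E8).  Group labels B..F are assigned
round-robin by scale rank, mimicking a small-to-large hospital grading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import PanelDataset

#: positivity floor; equals the scenario-module epsilon so that an
#: "already at epsilon" column is a genuine best-case no-op
EPS_FLOOR = 1e-6

VARIABLES = (
    "E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8", "E9",
    "Q1", "Q2", "Q3", "Q4", "Q5", "Q6", "Q7",
    "A1", "A2", "A3",
)

#: volume column bounding each event count
EVENT_BOUNDS = {
    "Q1": "E7", "Q2": "E7", "Q4": "E7", "Q5": "E7",
    "Q3": "E9", "Q6": "E9", "Q7": "E9", "A1": "E9",
    "A2": "E8",
}

#: per-volume event probabilities: appropriateness counts (Q1-Q3) are the
#: common case, adverse events (Q4-Q7) are rare, access shortfalls modest
DEFAULT_EVENT_RATES = {
    "Q1": 0.92,
    "Q2": 0.95,
    "Q3": 0.60,
    "Q4": 0.015,
    "Q5": 0.008,
    "Q6": 0.006,
    "Q7": 0.010,
    "A1": 0.030,
    "A2": 0.040,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; the defaults are the reference conditions."""

    n_dmus: int = 27
    n_periods: int = 4
    group_labels: tuple[str, ...] = ("B", "C", "D", "E", "F")
    size_spread: float = 6.0  # ratio of largest to smallest latent scale
    noise_cv: float = 0.10  # coefficient of variation of lognormal noise
    event_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATES)
    )
    #: (low, high) uniform range, or one factor per DMU; >= 1 always
    inefficiency: tuple[float, float] | tuple[float, ...] = (1.0, 1.4)
    #: pairs forced to a target Pearson correlation, e.g. {("E2","E3"): 0.99}
    correlation_targets: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("E2", "E3"): 0.99}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dmus < 1 or self.n_periods < 1:
            raise ValueError("n_dmus and n_periods must be >= 1")
        if self.size_spread < 1:
            raise ValueError("size_spread must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for var, rate in self.event_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"event rate for {var!r} must be in [0, 1]")
        ineff = np.asarray(self.inefficiency, dtype=float)
        if np.any(ineff < 1.0):
            raise ValueError("inefficiency factors must be >= 1")
        if ineff.shape not in ((2,), (self.n_dmus,)):
            raise ValueError(
                "inefficiency must be a (low, high) pair or one factor per DMU"
            )
        for rho in self.correlation_targets.values():
            if not 0.0 < rho < 1.0:
                raise ValueError("correlation targets must be in (0, 1)")


def _lognoise(rng, sigma, shape):
    """Mean-one lognormal noise."""
    if sigma == 0:
        return np.ones(shape)
    return rng.lognormal(-0.5 * sigma**2, sigma, shape)


def generate_panel(config: SyntheticConfig | None = None, **overrides) -> PanelDataset:
    """Draw a reproducible synthetic hospital panel.

    Same seed, same config -> bit-identical panel.  Keyword overrides are a
    shorthand for ``SyntheticConfig(**overrides)``.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_dmus, cfg.n_periods
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))

    # latent hospital scale, log-uniform over [1, size_spread]
    scale = np.exp(rng.uniform(0.0, np.log(cfg.size_spread), n))
    ineff = np.asarray(cfg.inefficiency, dtype=float)
    if ineff.shape == (2,) and n != 2:
        ineff = rng.uniform(ineff[0], ineff[1], n)
    elif ineff.shape == (2,) and n == 2:
        # ambiguous shape: a 2-vector for 2 DMUs is taken as per-DMU factors
        ineff = ineff.copy()
    s = scale[:, None] * np.ones((n, T))  # scale is persistent across periods

    cols: dict[str, np.ndarray] = {}
    cols["E1"] = 250.0 * s * _lognoise(rng, sigma, (n, T))  # beds
    cols["E2"] = 1.6e5 * cols["E1"] / 250.0 * _lognoise(rng, sigma, (n, T))
    cols["E3"] = 3.6e5 * cols["E1"] / 250.0 * _lognoise(rng, sigma, (n, T))
    staff = cols["E2"] + cols["E3"]
    cols["E4"] = 95.0 * staff * _lognoise(rng, sigma, (n, T))  # operational costs
    cols["E5"] = 80.0 * staff * _lognoise(rng, sigma, (n, T))  # personnel costs
    cols["E6"] = 0.25 * cols["E4"] * _lognoise(rng, sigma, (n, T))  # outsourcing

    out_scale = s / ineff[:, None]
    cols["E7"] = 12000.0 * out_scale * _lognoise(rng, sigma, (n, T))
    cols["E8"] = 90000.0 * out_scale * _lognoise(rng, sigma, (n, T))
    cols["E9"] = 6000.0 * out_scale * _lognoise(rng, sigma, (n, T))

    # calibrate requested correlation pairs: regenerate the second member
    # from the first with just enough independent noise to hit the target
    for (a, b), rho in cfg.correlation_targets.items():
        if a not in cols or b not in cols:
            raise KeyError(f"correlation target references unknown column ({a},{b})")
        la = np.log(cols[a])
        var_la = la.var()
        sigma_b = float(np.sqrt(max(var_la, 1e-12) * (1.0 / rho**2 - 1.0)))
        level = cols[b].mean() / cols[a].mean()
        cols[b] = level * cols[a] * _lognoise(rng, sigma_b, (n, T))

    for var in ("Q1", "Q2", "Q3", "Q4", "Q5", "Q6", "Q7", "A1", "A2"):
        rate = cfg.event_rates.get(var, DEFAULT_EVENT_RATES[var])
        trials = np.floor(cols[EVENT_BOUNDS[var]]).astype(np.int64)
        cols[var] = rng.binomial(np.maximum(trials, 0), rate).astype(float)

    # surgery waiting time in days, independent of scale
    cols["A3"] = rng.lognormal(np.log(90.0) - 0.5 * 0.3**2, 0.3, (n, T))

    values = np.stack([np.maximum(cols[v], EPS_FLOOR) for v in VARIABLES], axis=2)

    dmu_ids = tuple(f"H{i + 1:02d}" for i in range(n))
    periods = tuple(str(2016 + t) for t in range(T))
    ranks = np.argsort(np.argsort(scale))  # 0 = smallest
    labels = cfg.group_labels
    groups = {dmu_ids[i]: labels[ranks[i] % len(labels)] for i in range(n)}
    return PanelDataset(dmu_ids, periods, VARIABLES, values, groups)
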