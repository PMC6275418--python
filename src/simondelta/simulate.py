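"""Synthetic Simon-task trial generator with activation-suppression structure.

The generator produces long-format trial tables whose distributional
signatures follow the activation-suppression account of selective
response inhibition:

* Base reaction times are **ex-Gaussian** (normal + exponential) per
  subject and design cell, with normally distributed between-subject
  jitter on the three parameters — the standard positively skewed RT
  model.
* On incongruent trials the automatic location-driven response adds an
  **interference cost** that decays exponentially in the base RT:
  ``A * exp(-s * max(0, t - t0))``.  A positive suppression rate ``s``
  makes the Simon effect shrink for slow responses (negative-going
  delta-plot slope, effective late suppression); a negative ``s`` makes
  it grow (positive-going slope); ``s = 0`` leaves it flat.
* **Fast errors**: the probability that a trial is initiated with the
  wrong hand (kinematic error, KE) on incongruent trials decays in base
  RT, ``min(1, p0 * exp(-k * max(0, t - t0)))``, so errors concentrate in
  the fast bins of the conditional accuracy function.  Congruent trials
  have a small constant KE rate.  KE trials keep a valid RT, drawn from
  the base RT minus a fast-error advantage (impulsive direct-route
  responses are fast).
* Movement time for transport movements (reaching) is lognormal, and
  movement errors (ME) are independent Bernoulli events — both
  unaffected by congruence, as the Simon effect acts on response
  selection, not transport.

Everything is driven by a single seeded generator stream with subject
parameters drawn first, so the same config and seed reproduce a
bit-identical table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trials import (
    COLUMNS,
    TRANSPORT_MOVEMENTS,
    BlockSpec,
    ExperimentDesign,
)

__all__ = [
    "ExGaussParams",
    "InterferenceParams",
    "FastErrorParams",
    "MTModel",
    "GeneratorConfig",
    "interference_ms",
    "ke_probability",
    "simulate_experiment",
    "regime_presets",
    "preset",
    "PRESET_NAMES",
]

Cell = tuple[str, str]  # (selection_mode, movement)


@dataclass(frozen=True)
class ExGaussParams:
    """Ex-Gaussian RT parameters in ms: mean mu + sd sigma of the normal
    component, mean tau of the exponential component."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self):
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be positive")

    @property
    def mean(self) -> float:
        return self.mu + self.tau


@dataclass(frozen=True)
class InterferenceParams:
    """Additive incongruency cost ``A * exp(-s * max(0, t - t0))``.

    amplitude_ms
        Cost A (ms, >= 0) for base RTs at or below the onset.
    suppression_rate
        Decay rate s (1/ms); positive values suppress the cost for slow
        responses, negative values let it grow, zero keeps it flat.
    onset_ms
        Base RT t0 below which the cost is clamped at A.
    """

    amplitude_ms: float
    suppression_rate: float
    onset_ms: float

    def __post_init__(self):
        if self.amplitude_ms < 0:
            raise ValueError("amplitude_ms must be >= 0")


@dataclass(frozen=True)
class FastErrorParams:
    """Kinematic-error model: fast incongruent trials err most often.

    Incongruent KE probability is ``min(1, p0 * exp(-k * max(0, t - t0)))``
    in the base RT t; congruent trials use the constant base rate.
    """

    p0: float
    decay: float
    onset_ms: float
    congruent_base_rate: float

    def __post_init__(self):
        if not (0 <= self.p0 <= 1 and 0 <= self.congruent_base_rate <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class MTModel:
    """Lognormal movement time for transport movements."""

    median_ms: float
    sigma: float

    def __post_init__(self):
        if self.median_ms <= 0 or self.sigma <= 0:
            raise ValueError("median_ms and sigma must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one simulated experiment.

    Per-cell dictionaries are keyed by ``(selection_mode, movement)``.
    ``subject_jitter`` holds the between-subject standard deviations of
    the three ex-Gaussian parameters (one jitter triple per subject,
    shared across cells, creating a subject main effect).
    """

    design: ExperimentDesign
    base_rt: dict[Cell, ExGaussParams]
    interference: dict[Cell, InterferenceParams]
    fast_error: dict[Cell, FastErrorParams]
    mt_model: dict[str, MTModel] = field(default_factory=dict)
    me_rate: dict[str, float] = field(default_factory=dict)
    subject_jitter: ExGaussParams = ExGaussParams(mu=25.0, sigma=8.0, tau=15.0)
    ke_rt_advantage_ms: float = 60.0
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return self.design.n_subjects

    def cells(self) -> list[Cell]:
        out: list[Cell] = []
        for block in self.design.blocks:
            for movement in block.movements:
                cell = (block.selection_mode, movement)
                if cell not in out:
                    out.append(cell)
        return out

    def validate(self) -> None:
        for cell in self.cells():
            for name, table in (("base_rt", self.base_rt),
                                ("interference", self.interference),
                                ("fast_error", self.fast_error)):
                if cell not in table:
                    raise ValueError(f"{name} has no entry for cell {cell}")
        for movement in {m for _, m in self.cells()} & TRANSPORT_MOVEMENTS:
            if movement not in self.mt_model:
                raise ValueError(f"mt_model missing for transport movement "
                                 f"{movement!r}")
        for rate in self.me_rate.values():
            if not 0 <= rate <= 1:
                raise ValueError("me_rate values must lie in [0, 1]")


def interference_ms(t, params: InterferenceParams):
    """Incongruency cost (ms) at base RT ``t``: A*exp(-s*max(0, t - t0))."""
    t = np.asarray(t, dtype=float)
    lag = np.maximum(0.0, t - params.onset_ms)
    out = params.amplitude_ms * np.exp(-params.suppression_rate * lag)
    return float(out) if out.ndim == 0 else out


def ke_probability(t, congruence: str, params: FastErrorParams):
    """Probability of a kinematic error at base RT ``t``.

    Non-increasing in ``t`` on incongruent trials for ``decay >= 0``;
    constant on congruent trials.
    """
    t = np.asarray(t, dtype=float)
    if congruence == "congruent":
        out = np.full(t.shape, params.congruent_base_rate)
    elif congruence == "incongruent":
        lag = np.maximum(0.0, t - params.onset_ms)
        out = np.minimum(1.0, params.p0 * np.exp(-params.decay * lag))
    else:
        raise ValueError(f"unknown congruence {congruence!r}")
    return float(out) if out.ndim == 0 else out


def _balanced_conditions(block: BlockSpec, rng: np.random.Generator):
    """Movement x congruence sequence for one block, balanced and shuffled."""
    combos = [(m, c) for m in block.movements
              for c in ("congruent", "incongruent")]
    reps = -(-block.n_trials // len(combos))  # ceil
    seq = (combos * reps)[: block.n_trials]
    order = rng.permutation(len(seq))
    return [seq[i] for i in order]


def simulate_experiment(config: GeneratorConfig
                        ) -> tuple[pd.DataFrame, dict]:
    """Draw a full trial table plus a ground-truth sidecar.

    Subject-level ex-Gaussian jitter is drawn first, then trials subject
    by subject and block by block in a fixed order from one seeded
    stream; the output is bit-reproducible for a given config and seed
    and passes :func:`simondelta.trials.validate_trials` with zero
    problems.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    jit = config.subject_jitter
    subject_ids = [f"s{i + 1:02d}" for i in range(config.n_subjects)]
    subject_params: dict[str, dict] = {}
    for sid in subject_ids:
        subject_params[sid] = {
            "mu_jitter": float(rng.normal(0.0, jit.mu)),
            "sigma_jitter": float(rng.normal(0.0, jit.sigma)),
            "tau_jitter": float(rng.normal(0.0, jit.tau)),
        }

    rows: list[dict] = []
    for sid in subject_ids:
        sp = subject_params[sid]
        trial_no = 0
        for block in config.design.blocks:
            conditions = _balanced_conditions(block, rng)
            for movement, congruence in conditions:
                trial_no += 1
                cell = (block.selection_mode, movement)
                base = config.base_rt[cell]
                mu = base.mu + sp["mu_jitter"]
                sigma = max(5.0, base.sigma + sp["sigma_jitter"])
                tau = max(5.0, base.tau + sp["tau_jitter"])
                t = rng.normal(mu, sigma) + rng.exponential(tau)
                t = max(60.0, t)

                p_ke = ke_probability(t, congruence, config.fast_error[cell])
                ke = bool(rng.random() < p_ke)
                if ke:
                    # impulsive direct-route response: fast, no added cost
                    rt = max(60.0, t - config.ke_rt_advantage_ms)
                elif congruence == "incongruent":
                    rt = t + interference_ms(t, config.interference[cell])
                else:
                    rt = t

                stimulus_side = "left" if rng.random() < 0.5 else "right"
                if congruence == "congruent":
                    response_hand = stimulus_side
                else:
                    response_hand = "right" if stimulus_side == "left" else "left"

                if movement in TRANSPORT_MOVEMENTS:
                    mtm = config.mt_model[movement]
                    mt = float(rng.lognormal(np.log(mtm.median_ms), mtm.sigma))
                    me = bool(rng.random() < config.me_rate.get(movement, 0.0))
                else:
                    mt = np.nan
                    me = False

                rows.append({
                    "subject_id": sid,
                    "selection_mode": block.selection_mode,
                    "movement": movement,
                    "congruence": congruence,
                    "stimulus_side": stimulus_side,
                    "response_hand": response_hand,
                    "rt_ms": round(float(rt), 3),
                    "mt_ms": round(mt, 3) if np.isfinite(mt) else np.nan,
                    "ke": ke,
                    "me": me,
                    "trial_index": trial_no,
                })
    table = pd.DataFrame(rows, columns=COLUMNS)
    truth = {
        "seed": config.seed,
        "config": _config_to_dict(config),
        "subject_params": subject_params,
    }
    return table, truth


def _config_to_dict(config: GeneratorConfig) -> dict:
    def cellkey(cell):
        return "/".join(cell) if isinstance(cell, tuple) else cell

    out = dataclasses.asdict(config)
    for name in ("base_rt", "interference", "fast_error"):
        out[name] = {cellkey(k): dataclasses.asdict(v)
                     for k, v in getattr(config, name).items()}
    out["mt_model"] = {k: dataclasses.asdict(v)
                       for k, v in config.mt_model.items()}
    out["subject_jitter"] = dataclasses.asdict(config.subject_jitter)
    out["design"] = {
        "n_subjects": config.design.n_subjects,
        "practice_trials": config.design.practice_trials,
        "blocks": [{"selection_mode": b.selection_mode,
                    "movements": list(b.movements),
                    "n_trials": b.n_trials} for b in config.design.blocks],
    }
    return out


# ---------------------------------------------------------------------------
# Regime presets: the qualitative parameter regimes of the four study
# designs.  Sizes follow the original designs (16 subjects; 144 trials per
# single-movement block, 288 in mixed blocks); amplitudes and base RTs are
# set so cell means land near the reported values, and the signs of the
# suppression rates reproduce each design's delta-plot slope pattern.
# ---------------------------------------------------------------------------

PRESET_NAMES = ("exp1_like", "exp2_like", "exp3_like", "exp4_like")

_NOACT_LIFT = InterferenceParams(amplitude_ms=45.0, suppression_rate=0.004,
                                 onset_ms=250.0)
_NOACT_REACH = InterferenceParams(amplitude_ms=40.0, suppression_rate=0.002,
                                  onset_ms=300.0)
_ACT_LIFT = InterferenceParams(amplitude_ms=60.0, suppression_rate=0.004,
                               onset_ms=350.0)
_ACT_REACH = InterferenceParams(amplitude_ms=45.0, suppression_rate=-0.0015,
                                onset_ms=250.0)

_FE_BASE = FastErrorParams(p0=0.15, decay=0.008, onset_ms=200.0,
                           congruent_base_rate=0.02)
_FE_LIFT_ACTIVE = FastErrorParams(p0=0.25, decay=0.004, onset_ms=300.0,
                                  congruent_base_rate=0.02)
_FE_REACH_ACTIVE = FastErrorParams(p0=0.15, decay=0.010, onset_ms=300.0,
                                   congruent_base_rate=0.02)

_MT = {"reaching": MTModel(median_ms=300.0, sigma=0.25)}
_ME = {"reaching": 0.01}


def _design(blocks, n_subjects=16):
    return ExperimentDesign(n_subjects=n_subjects,
                            blocks=tuple(BlockSpec(*b) for b in blocks))


def regime_presets(seed: int = 0, n_subjects: int = 16,
                   trial_factor: int = 1) -> dict[str, GeneratorConfig]:
    """The four named generator regimes.

    ``trial_factor`` scales every block's trial count (the block structure
    and parameters are unchanged) for Monte-Carlo tests that need tighter
    error bars than the desk-scale designs provide.
    """
    f = trial_factor

    exp1 = GeneratorConfig(
        design=_design([("no_active", ("lifting",), 144 * f),
                        ("no_active", ("reaching",), 144 * f)], n_subjects),
        base_rt={("no_active", "lifting"): ExGaussParams(292.0, 40.0, 80.0),
                 ("no_active", "reaching"): ExGaussParams(405.0, 40.0, 80.0)},
        interference={("no_active", "lifting"): _NOACT_LIFT,
                      ("no_active", "reaching"): _NOACT_REACH},
        fast_error={("no_active", "lifting"): _FE_BASE,
                    ("no_active", "reaching"): _FE_BASE},
        mt_model=dict(_MT), me_rate=dict(_ME), seed=seed,
    )

    exp2 = GeneratorConfig(
        design=_design([("active", ("lifting", "reaching"), 288 * f)],
                       n_subjects),
        base_rt={("active", "lifting"): ExGaussParams(566.0, 40.0, 80.0),
                 ("active", "reaching"): ExGaussParams(483.0, 40.0, 80.0)},
        interference={("active", "lifting"): _ACT_LIFT,
                      ("active", "reaching"): _ACT_REACH},
        fast_error={("active", "lifting"): _FE_LIFT_ACTIVE,
                    ("active", "reaching"): _FE_REACH_ACTIVE},
        mt_model=dict(_MT), me_rate=dict(_ME), seed=seed,
    )

    exp3 = GeneratorConfig(
        design=_design([("no_active", ("lifting",), 144 * f),
                        ("no_active", ("reaching",), 144 * f),
                        ("active", ("lifting", "reaching"), 288 * f)],
                       n_subjects),
        base_rt={**exp1.base_rt, **exp2.base_rt},
        interference={**exp1.interference, **exp2.interference},
        fast_error={**exp1.fast_error, **exp2.fast_error},
        mt_model=dict(_MT), me_rate=dict(_ME), seed=seed,
    )

    # Two lifting variants with identical parameters in every cell: equal
    # movement complexity, so no activation or suppression difference.
    lift4_no = ExGaussParams(358.0, 40.0, 80.0)
    lift4_act = ExGaussParams(558.0, 40.0, 80.0)
    intf4_no = InterferenceParams(amplitude_ms=45.0, suppression_rate=0.003,
                                  onset_ms=300.0)
    intf4_act = InterferenceParams(amplitude_ms=50.0, suppression_rate=0.003,
                                   onset_ms=500.0)
    fe4 = FastErrorParams(p0=0.18, decay=0.006, onset_ms=250.0,
                          congruent_base_rate=0.02)
    exp4 = GeneratorConfig(
        design=_design([("no_active", ("index_lifting",), 144 * f),
                        ("no_active", ("little_lifting",), 144 * f),
                        ("active", ("index_lifting", "little_lifting"),
                         288 * f)], n_subjects),
        base_rt={("no_active", "index_lifting"): lift4_no,
                 ("no_active", "little_lifting"): lift4_no,
                 ("active", "index_lifting"): lift4_act,
                 ("active", "little_lifting"): lift4_act},
        interference={("no_active", "index_lifting"): intf4_no,
                      ("no_active", "little_lifting"): intf4_no,
                      ("active", "index_lifting"): intf4_act,
                      ("active", "little_lifting"): intf4_act},
        fast_error={("no_active", "index_lifting"): fe4,
                    ("no_active", "little_lifting"): fe4,
                    ("active", "index_lifting"): fe4,
                    ("active", "little_lifting"): fe4},
        seed=seed,
    )
    return {"exp1_like": exp1, "exp2_like": exp2,
            "exp3_like": exp3, "exp4_like": exp4}


def preset(name: str, seed: int = 0, n_subjects: int = 16,
           trial_factor: int = 1) -> GeneratorConfig:
    """Look up one named regime preset (see :func:`regime_presets`)."""
    presets = regime_presets(seed=seed, n_subjects=n_subjects,
                             trial_factor=trial_factor)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return presets[name]
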