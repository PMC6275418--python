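"""Shared fixtures: hand-built trial rows and small simulated tables."""

from __future__ import annotations

import pandas as pd
import pytest

from simondelta.trials import COLUMNS


def make_trials(rows: list[dict]) -> pd.DataFrame:
    """Build a trial table from partial row dicts, filling valid defaults.

    Defaults describe a correct congruent lifting trial; ``stimulus_side``
    and ``response_hand`` are derived from congruence unless given.
    """
    out = []
    for i, row in enumerate(rows):
        base = {
            "subject_id": "s01",
            "selection_mode": "no_active",
            "movement": "lifting",
            "congruence": "congruent",
            "stimulus_side": "left",
            "rt_ms": 400.0,
            "mt_ms": float("nan"),
            "ke": False,
            "me": False,
            "trial_index": i + 1,
        }
        base.update(row)
        if "response_hand" not in base:
            if base["congruence"] == "congruent":
                base["response_hand"] = base["stimulus_side"]
            else:
                base["response_hand"] = ("right" if base["stimulus_side"] == "left"
                                         else "left")
        out.append(base)
    return pd.DataFrame(out, columns=COLUMNS)


@pytest.fixture(scope="session")
def exp2_table():
    """Desk-scale simulated mixed-block experiment (fixed seed)."""
    from simondelta.simulate import preset, simulate_experiment

    table, truth = simulate_experiment(preset("exp2_like", seed=42))
    return table


@pytest.fixture(scope="session")
def exp1_table():
    from simondelta.simulate import preset, simulate_experiment

    table, truth = simulate_experiment(preset("exp1_like", seed=42))
    return table
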