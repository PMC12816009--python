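"""Published link-scale audit coefficients used as reconstruction inputs.

Intercepts of a published distributional bias audit of four soft-voting
ensemble configurations of automatic sleep stagers — a heterogeneous
all-architecture ensemble (E) and three architecture-restricted
ensembles (E1, E2, E3) — evaluated on a large clinical sleep registry.
The baseline subject of that audit is a 50-year-old female with
AHI = PLMI = 0, at which every linear predictor reduces to its
intercept, so the table below suffices to reconstruct the baseline
performance and marker-bias profiles via the inverse links
(see :func:`sleepeval.biasgamlss.baseline_profile`).

Bounded performance metrics (macro-F1) follow the inflated-Beta family:
``mu``/``sigma`` on the logit scale, inflation intercepts ``log_nu`` /
``log_tau`` on the log scale. Marker-difference outcomes (prediction
minus reference) follow the Normal family: ``mu`` in the marker's units
(minutes, events/hour), ``sigma`` on the log scale.
"""

from __future__ import annotations

ENSEMBLE_MODELS = ("E", "E1", "E2", "E3")

#: Macro-F1 audit blocks (inflated-Beta family, link scale).
MF1_AUDIT: dict[str, dict[str, float]] = {
    "E": {"mu": 1.12, "sigma": -1.51, "log_nu": -22.54, "log_tau": -22.63},
    "E1": {"mu": 1.06, "sigma": -1.46, "log_nu": -22.54, "log_tau": -22.63},
    "E2": {"mu": 1.05, "sigma": -1.47, "log_nu": -22.54, "log_tau": -22.63},
    "E3": {"mu": 1.13, "sigma": -1.53, "log_nu": -21.54, "log_tau": -21.63},
}

#: Macro-F1 location covariate effects of the heterogeneous ensemble (E),
#: logit scale, used as a generating model in recovery studies.
MF1_E_GENERATING_MODEL: dict = {
    "mu": {"intercept": 1.12, "gender": -0.06, "ahi10": -0.05},
    "sigma": {"intercept": -1.51},
    "log_nu": -22.54,
    "log_tau": -22.63,
}

#: Marker-difference audit intercepts (Normal family; mu in marker units,
#: sigma on the log scale).
MARKER_AUDIT: dict[str, dict[str, dict[str, float]]] = {
    "TST": {  # minutes
        "E": {"mu": -9.05, "sigma": 2.86},
        "E1": {"mu": -8.11, "sigma": 2.88},
        "E2": {"mu": -8.98, "sigma": 2.88},
        "E3": {"mu": -9.96, "sigma": 2.88},
    },
    "REM": {  # minutes
        "E": {"mu": 4.33, "sigma": 2.42},
        "E1": {"mu": 2.60, "sigma": 2.43},
        "E2": {"mu": 3.21, "sigma": 2.39},
        "E3": {"mu": 5.61, "sigma": 2.47},
    },
    "AwH": {  # events per hour
        "E": {"mu": 0.32, "sigma": 0.03},
        "E1": {"mu": 0.25, "sigma": 0.05},
        "E2": {"mu": 0.34, "sigma": 0.03},
        "E3": {"mu": 0.40, "sigma": 0.05},
    },
}
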