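"""Probabilistic sensitivity analysis.

Each iteration draws one complete parameter realisation (beta draws for the
seven event probabilities, Dirichlet draws for the six MOD distributions;
unit costs stay fixed), evaluates *both* strategies on that same realisation,
and records per-patient expectations plus the incremental quantities
(universal minus selective).  Summaries report means with equal-tailed 95%
credibility intervals (empirical 2.5/97.5 percentiles, linear interpolation
between order statistics) and population-scaled annual counts.

Two ICER estimators are computed: the ratio of mean incremental cost to mean
incremental QALYs, and the mean of per-iteration ratios.  Iterations whose
incremental QALY (or, for number-needed-to-scan per death averted, whose
mortality reduction) is not positive are excluded from ratio-based summaries
only, with their count logged; they remain in all arithmetic means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .parameters import (
    ENDPOINT_CLASSES,
    EconSettings,
    ModelParameters,
    sample_draw,
    validate,
)
from .tree import evaluate_strategy

__all__ = [
    "run_psa",
    "summarize",
    "icer",
    "scans_per_detection",
    "scans_per_death_averted",
]

logger = logging.getLogger(__name__)

_ARM_PREFIX = {"universal": "uni", "selective": "sel"}


def run_psa(
    params: ModelParameters, n_iter: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Run the PSA; returns one row per iteration.

    Both strategies are evaluated on the same draw within an iteration.  The
    run is bit-reproducible for a given seed: parameters are sampled in the
    fixed order documented in :func:`breechcea.parameters.sample_draw`.

    Columns: the sampled prevalence and detection probability; per-arm cost
    components, endpoint probabilities, mortality and QALYs (prefixes
    ``uni_``/``sel_``); incremental quantities ``inc_cost``, ``inc_qaly``,
    ``inc_mortality`` (universal - selective); the per-iteration ICER (NaN
    where the incremental QALY is not positive); and the per-iteration
    number-needed-to-scan quantities.
    """
    violations = validate(params)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(violations))
    n = int(params.econ.psa_iterations if n_iter is None else n_iter)
    if n < 1:
        raise ValueError("n_iter must be >= 1")
    if seed is None:
        seed = params.econ.random_seed
    rng = np.random.default_rng(seed)

    draw = sample_draw(params, rng, size=n)
    results = {
        arm: evaluate_strategy(arm, draw, params.econ) for arm in _ARM_PREFIX
    }

    data: dict[str, np.ndarray] = {
        "iteration": np.arange(n),
        "p_breech": np.atleast_1d(draw.p_breech),
        "p_detect": np.atleast_1d(draw.p_detect),
    }
    for arm, prefix in _ARM_PREFIX.items():
        res = results[arm]
        data[f"{prefix}_cost_total"] = res.cost_total
        data[f"{prefix}_cost_screening"] = res.cost_screening
        data[f"{prefix}_cost_ecv"] = res.cost_ecv
        data[f"{prefix}_cost_delivery"] = res.cost_delivery
        data[f"{prefix}_cost_mortality"] = res.cost_mortality
        data[f"{prefix}_p_mortality"] = res.p_mortality
        data[f"{prefix}_qaly"] = res.expected_qaly
        for j, cls in enumerate(ENDPOINT_CLASSES):
            data[f"{prefix}_ep_{cls}"] = res.endpoint[..., j]

    uni, sel = results["universal"], results["selective"]
    inc_cost = uni.cost_total - sel.cost_total
    inc_qaly = uni.expected_qaly - sel.expected_qaly
    inc_mortality = uni.p_mortality - sel.p_mortality
    data["inc_cost"] = inc_cost
    data["inc_qaly"] = inc_qaly
    data["inc_mortality"] = inc_mortality
    data["icer"] = np.where(inc_qaly > 0, inc_cost / np.where(inc_qaly > 0, inc_qaly, 1.0), np.nan)
    detection = np.atleast_1d(draw.p_breech) * (1 - np.atleast_1d(draw.p_detect))
    data["detection_rate"] = detection
    data["scans_per_detection"] = 1.0 / detection
    averted = -inc_mortality
    data["scans_per_death_averted"] = np.where(
        averted > 0, 1.0 / np.where(averted > 0, averted, 1.0), np.nan
    )
    return pd.DataFrame(data)


def _mean_cri(x) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    lo, hi = np.percentile(x, [2.5, 97.5])
    return {"mean": float(x.mean()), "cri": [float(lo), float(hi)]}


def icer(samples: pd.DataFrame) -> dict:
    """Both ICER estimators over the PSA samples.

    ``ratio_of_means`` divides the mean incremental cost by the mean
    incremental QALY; ``mean_of_ratios`` averages per-iteration ratios over
    the iterations with a positive incremental QALY (``n_excluded`` counts
    the rest, which is logged when non-zero).  ``ratio_cri`` is the 2.5/97.5
    percentile interval of the per-iteration ratios.
    """
    inc_cost = samples["inc_cost"].to_numpy()
    inc_qaly = samples["inc_qaly"].to_numpy()
    valid = inc_qaly > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning(
            "ICER: excluded %d/%d iterations with non-positive incremental QALY "
            "from ratio-based summaries", n_excluded, len(samples)
        )
    mean_qaly = inc_qaly.mean()
    if mean_qaly == 0:
        raise ValueError("mean incremental QALY is zero; ratio of means undefined")
    ratios = inc_cost[valid] / inc_qaly[valid]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return {
        "ratio_of_means": float(inc_cost.mean() / mean_qaly),
        "mean_of_ratios": float(ratios.mean()),
        "ratio_cri": [float(lo), float(hi)],
        "n_excluded": n_excluded,
    }


def scans_per_detection(samples: pd.DataFrame) -> dict:
    """Scans needed per previously undetected breech found: the mean and CrI
    of per-iteration ``1 / (prevalence * undetected fraction)``."""
    return _mean_cri(samples["scans_per_detection"])


def scans_per_death_averted(samples: pd.DataFrame) -> dict:
    """Scans needed per neonatal death averted, over iterations where
    universal screening lowers mortality (the rest excluded and counted)."""
    col = samples["scans_per_death_averted"]
    n_excluded = int(col.isna().sum())
    if n_excluded:
        logger.warning(
            "scans per death averted: excluded %d/%d iterations with no "
            "mortality reduction", n_excluded, len(samples)
        )
    out = _mean_cri(col)
    out["n_excluded"] = n_excluded
    return out


def summarize(samples: pd.DataFrame, econ: EconSettings) -> dict:
    """Means and 95% credibility intervals of all tracked quantities, plus
    population-scaled annual counts and both ICER estimators (JSON-ready)."""
    if len(samples) < 2:
        raise ValueError("summarize requires at least 2 PSA samples")
    pop = econ.population_size
    per_patient: dict = {}
    for arm in ("uni", "sel"):
        name = "universal" if arm == "uni" else "selective"
        per_patient[name] = {
            key: _mean_cri(samples[f"{arm}_{key}"])
            for key in (
                "cost_total",
                "cost_screening",
                "cost_ecv",
                "cost_delivery",
                "cost_mortality",
                "p_mortality",
                "qaly",
            )
        }
        per_patient[name]["endpoint"] = {
            cls: float(samples[f"{arm}_ep_{cls}"].mean()) for cls in ENDPOINT_CLASSES
        }
    per_patient["incremental"] = {
        "cost": _mean_cri(samples["inc_cost"]),
        "qaly": _mean_cri(samples["inc_qaly"]),
        "mortality": _mean_cri(samples["inc_mortality"]),
        "endpoint": {
            cls: float(
                (samples[f"uni_ep_{cls}"] - samples[f"sel_ep_{cls}"]).mean()
            )
            for cls in ENDPOINT_CLASSES
        },
    }

    ep_inc = per_patient["incremental"]["endpoint"]
    population = {
        "size": int(pop),
        "incremental_cost": _scale(_mean_cri(samples["inc_cost"]), pop),
        "deaths_averted_per_year": _scale(_mean_cri(-samples["inc_mortality"]), pop),
        "qalys_gained_per_year": _scale(_mean_cri(samples["inc_qaly"]), pop),
        "detections_per_year": _scale(_mean_cri(samples["detection_rate"]), pop),
        "elcs_added_per_year": pop
        * (ep_inc["cephalic_elcs"] + ep_inc["breech_elcs"]),
        "emcs_avoided_per_year": -pop
        * (ep_inc["cephalic_emcs"] + ep_inc["breech_emcs"]),
        "vb_avoided_per_year": -pop * ep_inc["vaginal_breech"],
    }
    return {
        "n_iterations": int(len(samples)),
        "per_patient": per_patient,
        "population": population,
        "icer": icer(samples),
        "scans_per_detection": scans_per_detection(samples),
        "scans_per_death_averted": scans_per_death_averted(samples),
    }


def _scale(mc: dict, factor: float) -> dict:
    return {
        "mean": mc["mean"] * factor,
        "cri": [mc["cri"][0] * factor, mc["cri"][1] * factor],
    }
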