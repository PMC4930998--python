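"""Conversion between engine units and biological units.

Engine units: sizes relative to the ancestral effective size ``N_A``, times
in ``2 N_A`` generations, migration as ``M = 2 N_A m``.  Calibration follows
the newt study's arithmetic: the per-generation mutation rate comes from
outgroup divergence ``d`` over a split ``2 * split_years / gen_years``
generations of total branch, ``N_A = theta / (4 mu L)``, and the effective
number of migrants per generation is the raw migration fraction times the
present-day diploid effective size of the recipient species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import DemographicModel, model_registry

__all__ = [
    "CalibrationInputs",
    "mutation_rate",
    "ancestral_size",
    "physical_params",
    "engine_params",
    "effective_migrants",
]


@dataclass(frozen=True)
class CalibrationInputs:
    """External calibration constants for unit conversion.

    divergence: per-site sequence divergence from the outgroup.
    split_years: age of the in-group/outgroup split in years.
    gen_years: generation time in years.
    L: effective sequence length (callable bases) behind theta.
    """

    divergence: float
    split_years: float = 18.4e6
    gen_years: float = 4.0
    L: float = 1.0

    def __post_init__(self):
        for name in ("divergence", "split_years", "gen_years", "L"):
            if getattr(self, name) < 0 or (name != "divergence" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    @property
    def mu(self) -> float:
        return mutation_rate(self.divergence, self.split_years, self.gen_years)


def mutation_rate(d: float, split_years: float, gen_years: float) -> float:
    """Per-bp per-generation mutation rate from outgroup divergence.

    ``mu = d / (2 * split_years / gen_years)``: divergence accumulates along
    both branches since the outgroup split.
    """
    return d / (2.0 * split_years / gen_years)


def ancestral_size(theta: float, mu: float, L: float) -> float:
    """Ancestral diploid effective size ``N_A = theta / (4 mu L)``."""
    return theta / (4.0 * mu * L)


def effective_migrants(m_raw: float, ne_recipient: float) -> float:
    """Effective number of immigrant individuals per generation.

    ``m_raw`` is the per-generation fraction of the recipient population made
    up of new migrants; multiplied by the recipient's present-day diploid
    effective size it gives immigrants per generation.
    """
    if m_raw < 0 or ne_recipient < 0:
        raise ValueError("inputs must be nonnegative")
    return m_raw * ne_recipient


def physical_params(model: DemographicModel | str, params, theta: float,
                    calib: CalibrationInputs) -> pd.DataFrame:
    """Convert a fitted parameter vector to biological units.

    Sizes become diploid individuals, times years, migration per-generation
    fractions; derived rows give the total divergence time and, for each
    migration rate, the effective number of migrants per generation into the
    recipient species (using the recipient's present-day size).
    """
    if isinstance(model, str):
        model = model_registry(model)
    p = dict(zip(model.param_names, np.asarray(params, dtype=float)))
    mu = calib.mu
    N_A = ancestral_size(theta, mu, calib.L)
    present = model.epochs(params, 0)[-1].end  # (nu1, nu2) now
    rows = [("N_A", N_A)]
    time_sum = 0.0
    for name, value in p.items():
        if name == "s" or name == "P":
            rows.append((name, value))
        elif name.startswith("nu"):
            rows.append((f"Ne_{name}", value * N_A))
        elif name.startswith("T"):
            years = value * 2.0 * N_A * calib.gen_years
            time_sum += years
            rows.append((f"{name}_years", years))
        elif name.startswith("m"):
            m_raw = value / (2.0 * N_A)
            rows.append((f"{name}_raw", m_raw))
            # m12*: into population 1 (Lv); m21*: into population 2 (Lm)
            recipient = present[0] if name.startswith("m12") else present[1]
            rows.append((f"migrants_{name}", effective_migrants(m_raw, recipient * N_A)))
    rows.append(("divergence_time_years", time_sum))
    rows.append(("Ne_pop1_present", present[0] * N_A))
    rows.append(("Ne_pop2_present", present[1] * N_A))
    return pd.DataFrame(rows, columns=["parameter", "value"])


def engine_params(model: DemographicModel | str, physical: dict, N_A: float,
                  gen_years: float) -> np.ndarray:
    """Inverse conversion: physical values back to an engine-unit vector.

    ``physical`` maps parameter names to biological values: ``Ne_<nu name>``
    in diploids, ``<T name>_years`` in years, ``<m name>_raw`` as raw
    per-generation fractions, ``s``/``P`` unchanged.  Exact inverse of
    :func:`physical_params` given the same ``N_A``.
    """
    if isinstance(model, str):
        model = model_registry(model)
    out = []
    for name in model.param_names:
        if name in ("s", "P"):
            out.append(physical[name])
        elif name.startswith("nu"):
            out.append(physical[f"Ne_{name}"] / N_A)
        elif name.startswith("T"):
            out.append(physical[f"{name}_years"] / (2.0 * N_A * gen_years))
        elif name.startswith("m"):
            out.append(physical[f"{name}_raw"] * 2.0 * N_A)
        else:  # pragma: no cover - registry names are exhaustive
            raise KeyError(name)
    return np.array(out)
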