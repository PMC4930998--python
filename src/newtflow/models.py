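"""Registry of the 16 two-population divergence models.

All models share a common skeleton: a single ancestral population of (scaled)
size 1 splits instantaneously into population 1 (*L. vulgaris*) and population
2 (*L. montandoni*); the descendants then pass through one or two epochs that
differ in population-size law (constant or exponential) and in migration.

Four scenario classes are covered, each with a homogeneous and a heterogeneous
(two migration classes across the genome, ``*HET``) variant:

* strict isolation -- ``SI`` (constant sizes), ``SIG`` (exponential change);
* ancient migration -- ``AM``/``AMHET`` (gene flow first, then isolation);
* secondary contact -- ``SC``/``SCHET`` (constant sizes), ``SCG``/``SCGHET``
  (exponential change in both epochs), ``SCIG``/``SCIGHET`` (change only
  during isolation), ``SCMG``/``SCMGHET`` (change only during migration);
* isolation with migration -- ``IM``/``IMHET`` (constant), ``IMG``/``IMGHET``
  (exponential change).

Units (engine units throughout):

* sizes ``nu`` are relative to the ancestral size ``N_A`` (diploids);
* times are in units of ``2 N_A`` generations;
* migration rates are ``M_ij = 2 N_A m_ij`` where ``m_ij`` is the per-
  generation fraction of population *i* made up of new migrants from
  population *j*;
* ``s`` is the fraction of the ancestral population founding population 2
  (L. montandoni); population 1 starts at ``1 - s``;
* ``P`` is the genome fraction belonging to migration class 1.

Models carrying ``s`` start the descendants at sizes ``(1 - s, s)``; the
others start them directly at their first-epoch sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["Epoch", "DemographicModel", "model_registry", "MODEL_NAMES"]


@dataclass(frozen=True)
class Epoch:
    """One forward-time epoch after the split.

    ``start``/``end`` are (pop1, pop2) sizes at the older/younger boundary;
    sizes change exponentially within the epoch when they differ.  ``mig`` is
    the pair ``(M12, M21)`` of scaled migration rates active in the epoch.
    """

    duration: float
    start: tuple[float, float]
    end: tuple[float, float]
    mig: tuple[float, float] = (0.0, 0.0)

    @property
    def has_growth(self) -> bool:
        return self.start != self.end


@dataclass(frozen=True)
class DemographicModel:
    """A named member of the model registry."""

    name: str
    param_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    het: bool
    _builder: Callable = field(repr=False)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def _pdict(self, params: Sequence[float]) -> dict:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"{self.name} expects {self.n_params} parameters "
                f"{self.param_names}, got {params.shape}"
            )
        return dict(zip(self.param_names, params))

    def epochs(self, params: Sequence[float], rate_class: int = 0) -> list[Epoch]:
        """Numeric epoch list for a parameter vector.

        For heterogeneous models ``rate_class`` selects migration class 0
        (weight ``P``) or 1 (weight ``1 - P``); homogeneous models accept
        only class 0.
        """
        p = self._pdict(params)
        if self.het:
            if rate_class not in (0, 1):
                raise ValueError("rate_class must be 0 or 1")
            suffix = "_1" if rate_class == 0 else "_2"
            rates = (p[f"m12{suffix}"], p[f"m21{suffix}"])
        else:
            if rate_class != 0:
                raise ValueError(f"{self.name} is not a heterogeneous model")
            rates = (p.get("m12", 0.0), p.get("m21", 0.0))
        return self._builder(p, rates)

    def mixture_weight(self, params: Sequence[float]) -> float:
        """Weight ``P`` of migration class 0 (1.0 for homogeneous models)."""
        if not self.het:
            return 1.0
        return float(self._pdict(params)["P"])

    def split_time(self, params: Sequence[float]) -> float:
        return sum(e.duration for e in self.epochs(params))


# ---------------------------------------------------------------------------
# Builders.  Each returns the forward-ordered epoch list for one rate class.
# ---------------------------------------------------------------------------

def _si(p, rates):
    nu = (p["nu1"], p["nu2"])
    return [Epoch(p["T"], nu, nu)]


def _sig(p, rates):
    return [Epoch(p["T"], (1.0, 1.0), (p["nu1"], p["nu2"]))]


def _am(p, rates):
    nu = (p["nu1"], p["nu2"])
    return [Epoch(p["Tm"], nu, nu, rates), Epoch(p["Ti"], nu, nu)]


def _sc(p, rates):
    nu = (p["nu1"], p["nu2"])
    return [Epoch(p["Ti"], nu, nu), Epoch(p["Tm"], nu, nu, rates)]


def _scg(p, rates):
    start = (1.0 - p["s"], p["s"])
    mid = (p["nu1_mid"], p["nu2_mid"])
    now = (p["nu1"], p["nu2"])
    return [Epoch(p["Ti"], start, mid), Epoch(p["Tm"], mid, now, rates)]


def _scig(p, rates):
    start = (1.0 - p["s"], p["s"])
    mid = (p["nu1_mid"], p["nu2_mid"])
    return [Epoch(p["Ti"], start, mid), Epoch(p["Tm"], mid, mid, rates)]


def _scmg(p, rates):
    iso = (p["nu1_iso"], p["nu2_iso"])
    now = (p["nu1"], p["nu2"])
    return [Epoch(p["Ti"], iso, iso), Epoch(p["Tm"], iso, now, rates)]


def _im(p, rates):
    nu = (1.0 - p["s"], p["s"])
    return [Epoch(p["T"], nu, nu, rates)]


def _img(p, rates):
    start = (1.0 - p["s"], p["s"])
    now = (p["nu1"], p["nu2"])
    return [Epoch(p["T"], start, now, rates)]


# Bounds by parameter kind.
_B = {
    "nu": (1e-4, 100.0),
    "T": (1e-6, 10.0),
    "m": (0.0, 50.0),
    "s": (1e-3, 0.999),
    "P": (1e-3, 0.999),
}


def _kind(name: str) -> str:
    if name.startswith("nu"):
        return "nu"
    if name.startswith("T"):
        return "T"
    if name.startswith("m"):
        return "m"
    return name  # "s", "P"


def _make(name, base_params, builder, het):
    params = list(base_params)
    if het:
        params += ["m12_1", "m21_1", "m12_2", "m21_2", "P"]
    elif builder in (_am, _sc, _scg, _scig, _scmg, _im, _img):
        params += ["m12", "m21"]
    lo = tuple(_B[_kind(q)][0] for q in params)
    hi = tuple(_B[_kind(q)][1] for q in params)
    return DemographicModel(name, tuple(params), lo, hi, het, builder)


_REGISTRY = {
    m.name: m
    for m in [
        _make("SI", ["nu1", "nu2", "T"], _si, False),
        _make("SIG", ["nu1", "nu2", "T"], _sig, False),
        _make("AM", ["nu1", "nu2", "Tm", "Ti"], _am, False),
        _make("AMHET", ["nu1", "nu2", "Tm", "Ti"], _am, True),
        _make("SC", ["nu1", "nu2", "Ti", "Tm"], _sc, False),
        _make("SCHET", ["nu1", "nu2", "Ti", "Tm"], _sc, True),
        _make("SCG", ["s", "nu1_mid", "nu2_mid", "nu1", "nu2", "Ti", "Tm"], _scg, False),
        _make("SCGHET", ["s", "nu1_mid", "nu2_mid", "nu1", "nu2", "Ti", "Tm"], _scg, True),
        _make("SCIG", ["s", "nu1_mid", "nu2_mid", "Ti", "Tm"], _scig, False),
        _make("SCIGHET", ["s", "nu1_mid", "nu2_mid", "Ti", "Tm"], _scig, True),
        _make("SCMG", ["nu1_iso", "nu2_iso", "nu1", "nu2", "Ti", "Tm"], _scmg, False),
        _make("SCMGHET", ["nu1_iso", "nu2_iso", "nu1", "nu2", "Ti", "Tm"], _scmg, True),
        _make("IM", ["s", "T"], _im, False),
        _make("IMHET", ["s", "T"], _im, True),
        _make("IMG", ["s", "nu1", "nu2", "T"], _img, False),
        _make("IMGHET", ["s", "nu1", "nu2", "T"], _img, True),
    ]
}

MODEL_NAMES = tuple(_REGISTRY)


def model_registry(name: str) -> DemographicModel:
    """Look a model up by name (case-insensitive)."""
    try:
        return _REGISTRY[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; known models: {', '.join(MODEL_NAMES)}"
        ) from None
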