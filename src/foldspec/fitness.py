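"""Elongation-speed perturbation and fitness effects of specificity mutations.

A mutation that makes a folding more specific can stall ribosomes harder,
raising the ribosome density on ``p`` codons by ``q``-fold.  With baseline
elongation speed ``v`` (codons/s) on a gene of ``L`` codons, the mutant's
average speed is

    v' = L v / (L - p + p q),     dv = v' - v ~ (p - p q) v / L   (p << L)

so dv < 0 when q > 1 (slower elongation).  The fitness consequence is
evaluated by a three-component model of translational economics:

1. time cost — with a fixed pool of translating ribosomes, slower elongation
   on the gene delays synthesis of the whole proteome in proportion to the
   gene's share of translation (expression x length / proteome size);
2. speed-accuracy trade-off — tRNA selection trades efficiency against
   accuracy linearly, so a relative slowdown reduces the per-codon
   mistranslation rate by ``slope x dv/v``;
3. misfolding cost — a fixed fraction of mistranslated proteins misfold, and
   each misfolded molecule imposes a dosage-dependent fitness cost.

The selection coefficient is benefit(2+3) minus cost(1); both scale with the
number of molecules produced, so selection on folding specificity is strong
for highly expressed genes and effectively neutral (|s| < 1/Ne) for lowly
expressed ones.  All constants live in a shipped parameter file
(``data/fitness_params.yaml``, reproducing the cited yeast configuration);
they are configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ElongationParams",
    "FitnessParams",
    "delta_v",
    "fitness_effect",
    "selection_regime",
    "load_default_params",
]

_REQUIRED_KEYS = (
    "baseline_error_rate",
    "trade_off_slope",
    "misfolded_fraction",
    "misfolding_cost",
    "proteome_size_aa",
    "proteome_time_cost",
    "ne",
)


@dataclass(frozen=True)
class ElongationParams:
    """Perturbation geometry: p codons slowed q-fold on an L-codon gene."""

    p: float          # codons affected
    q: float          # ribosome-density fold-change on those codons
    length: float     # gene length, codons
    v: float = 20.0   # baseline elongation speed, codons/s

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("p must be >= 0")
        if self.q <= 0:
            raise ValueError("q must be > 0")
        if self.v <= 0:
            raise ValueError("v must be > 0")
        if self.length <= self.p * max(1.0, self.q):
            raise ValueError("gene too short for the perturbation (L <= p*max(1,q))")


@dataclass(frozen=True)
class FitnessParams:
    """Constants of the three-component fitness model (units in the data file).

    expression        protein molecules per cell of the focal gene
    baseline_error_rate  mistranslation probability per codon at speed v
    trade_off_slope   relative error change per relative speed change
    misfolded_fraction   fraction of mistranslated proteins that misfold
    misfolding_cost   fitness cost per misfolded molecule per cell
    proteome_size_aa  amino acids synthesized per cell cycle
    proteome_time_cost   fitness cost per relative increase in synthesis time
    ne                effective population size
    """

    expression: float
    baseline_error_rate: float
    trade_off_slope: float
    misfolded_fraction: float
    misfolding_cost: float
    proteome_size_aa: float
    proteome_time_cost: float
    ne: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"fitness parameter {name!r} must be positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], expression: float) -> "FitnessParams":
        missing = [k for k in _REQUIRED_KEYS if k not in mapping]
        if missing:
            raise KeyError(f"fitness configuration missing parameter(s): {missing}")
        return cls(expression=float(expression),
                   **{k: float(mapping[k]) for k in _REQUIRED_KEYS})

    @classmethod
    def from_yaml(cls, path: str | Path | None, expression: float) -> "FitnessParams":
        """Load constants from a YAML file (``None`` -> the shipped defaults)."""
        if path is None:
            return cls.from_mapping(load_default_params(), expression)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise KeyError(f"{path}: expected a key-value parameter file")
        return cls.from_mapping(data, expression)


def load_default_params() -> dict[str, float]:
    """The shipped yeast parameter configuration as a plain dict."""
    text = resources.files("foldspec").joinpath("data/fitness_params.yaml").read_text()
    return yaml.safe_load(text)


def delta_v(params: ElongationParams, form: str = "approximate") -> float:
    """Average elongation-speed change of the mutant, codons/s.

    ``exact``: dv = v(p - pq)/(L - p + pq) from v' = Lv/(L - p + pq);
    ``approximate``: dv = (p - pq) v / L, valid for p << L and pq << L.
    The sign is sign(1 - q) for p > 0.
    """
    p, q, L, v = params.p, params.q, params.length, params.v
    if form == "approximate":
        return (p - p * q) * v / L
    if form == "exact":
        den = L - p + p * q
        if den <= 0:
            raise ValueError("non-positive denominator L - p + pq")
        return v * (p - p * q) / den
    raise ValueError(f"form must be 'exact' or 'approximate', got {form!r}")


def fitness_effect(
    dv: float,
    fp: FitnessParams,
    length_codons: float = 400.0,
    baseline_speed: float = 20.0,
) -> float:
    """Selection coefficient s of an elongation-speed change ``dv``.

    s = accuracy/misfolding benefit - proteome-time cost, both linear in the
    relative speed change and in the molecules produced (expression x length):

        rel     = dv / v
        benefit = -rel * slope * error_rate * misfolded_fraction
                       * misfolding_cost * expression * L
        cost    = -rel * time_cost * expression * L / proteome_size

    s = 0 at dv = 0; for dv < 0 (slowdown), s increases with expression as
    long as the benefit coefficient dominates the time cost.
    """
    if baseline_speed <= 0 or length_codons <= 0:
        raise ValueError("baseline_speed and length_codons must be positive")
    rel = dv / baseline_speed
    per_molecule_codons = fp.expression * length_codons
    benefit = (
        -rel
        * fp.trade_off_slope
        * fp.baseline_error_rate
        * fp.misfolded_fraction
        * fp.misfolding_cost
        * per_molecule_codons
    )
    cost = -rel * fp.proteome_time_cost * per_molecule_codons / fp.proteome_size_aa
    return benefit - cost


def selection_regime(s: float, ne: float) -> str:
    """'selectable' iff |s| > 1/Ne; the boundary counts as effectively neutral."""
    if ne <= 0:
        raise ValueError("Ne must be positive")
    return "selectable" if abs(s) > 1.0 / ne else "effectively_neutral"
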