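"""Cost/benefit decomposition of selection coefficients.

The fitness effect S of expressing the aggregation-prone protein splits
into three environment-specific magnitudes, each weighted by how much
protein sits where:

    S = alpha * f_foci  +  beta * f_free * [Ura3p essential]
                        +  gamma * f_free * [Ura3p toxic]

* ``alpha`` — cost of forming the deposit itself (material
  sequestration, chaperone load); the only active term when Ura3p
  activity is dispensable (+uracil).
* ``beta`` — cost of the lost essential activity (-uracil).
* ``gamma`` — benefit of sequestering the toxin-producing activity
  (+5FOA).

``f_foci`` is the mean over aggregating-strain cells of the per-cell
fraction of fluorescence in foci; ``f_free`` is the apparent free-protein
fraction, mean cytosolic fluorescence of the aggregating strain over
mean total fluorescence of the soluble strain (whose protein is all
free).  Within one environment ``alpha`` is assumed medium-independent:
it is estimated from the +uracil competition and reused for the
-uracil and +5FOA media, where the residual selection is attributed to
the free-protein term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Medium, Strain, validate_cells

__all__ = [
    "PopulationFractions",
    "population_fractions",
    "estimate_alpha",
    "estimate_beta",
    "estimate_gamma",
    "predict_S",
    "FitnessDecomposition",
    "DecompositionResults",
]


@dataclass(frozen=True)
class PopulationFractions:
    """Protein-partition summary of one imaged population pair.

    ``f_foci`` in [0, 1]; ``f_free`` >= 0 (can exceed 1 if the
    aggregating strain out-expresses the soluble one)."""

    f_foci: float
    f_free: float
    n_agg: int
    n_sol: int

    def __post_init__(self):
        if not 0.0 <= self.f_foci <= 1.0:
            raise ValueError("f_foci must lie in [0, 1]")
        if self.f_free < 0:
            raise ValueError("f_free must be >= 0")
        if self.n_agg <= 0 or self.n_sol <= 0:
            raise ValueError("cell counts must be positive")


def population_fractions(agg_cells: pd.DataFrame, sol_cells: pd.DataFrame,
                         foci_cells_only: bool = False,
                         ratio_of_means: bool = False) -> PopulationFractions:
    """Compute f_foci and f_free from per-cell fluorescence tables.

    By default f_foci is the mean of per-cell ratios F_FOCI/F_TOTAL over
    *all* aggregating cells (foci-free cells contribute zero);
    ``ratio_of_means`` switches to sum(F_FOCI)/sum(F_TOTAL), and
    ``foci_cells_only`` restricts the average to cells that contain at
    least one focus.  f_free is always a ratio of population means,
    since cells cannot be paired across strains.
    """
    if len(agg_cells) == 0 or len(sol_cells) == 0:
        raise ValueError("both cell collections must be non-empty")
    validate_cells(agg_cells)
    validate_cells(sol_cells)
    if (agg_cells["f_total"] <= 0).any() or (sol_cells["f_total"] <= 0).any():
        raise ValueError("every F_TOTAL must be positive")
    agg = agg_cells
    if foci_cells_only:
        agg = agg_cells[agg_cells["f_foci"] > 0]
        if len(agg) == 0:
            raise ValueError("no foci-containing cells in the aggregating population")
    if ratio_of_means:
        f_foci = float(agg["f_foci"].sum() / agg["f_total"].sum())
    else:
        f_foci = float((agg["f_foci"] / agg["f_total"]).mean())
    f_free = float(agg_cells["f_cyto"].mean() / sol_cells["f_total"].mean())
    return PopulationFractions(f_foci=f_foci, f_free=f_free,
                               n_agg=len(agg_cells), n_sol=len(sol_cells))


def estimate_alpha(S_plus_ura: float, fr: PopulationFractions) -> float:
    """Deposit-formation cost: alpha = S(+Ura) / f_foci.

    Undefined when no protein is deposited (f_foci = 0): fitness cannot
    be attributed to absent deposits.
    """
    if fr.f_foci == 0:
        raise ZeroDivisionError("alpha undefined: f_foci is zero")
    return S_plus_ura / fr.f_foci


def estimate_beta(S_minus_ura: float, alpha: float, fr: PopulationFractions) -> float:
    """Loss-of-function cost: beta = (S(-Ura) - alpha * f_foci) / f_free."""
    if fr.f_free == 0:
        raise ZeroDivisionError("beta undefined: f_free is zero")
    return (S_minus_ura - alpha * fr.f_foci) / fr.f_free


def estimate_gamma(S_foa: float, alpha: float, fr: PopulationFractions) -> float:
    """Gain-of-protection benefit: gamma = (S(5FOA) - alpha * f_foci) / f_free."""
    if fr.f_free == 0:
        raise ZeroDivisionError("gamma undefined: f_free is zero")
    return (S_foa - alpha * fr.f_foci) / fr.f_free


def predict_S(alpha: float, beta: float, gamma: float,
              fr: PopulationFractions, medium: "Medium | str") -> float:
    """Forward model: S from the coefficients and the protein partition.

    The loss (beta) and gain (gamma) terms are never active together —
    one medium determines whether Ura3p activity is absent-essential,
    present-toxic, or irrelevant.
    """
    medium = Medium.parse(medium)
    s = alpha * fr.f_foci
    if medium is Medium.MINUS_URA:
        s += beta * fr.f_free
    elif medium is Medium.FOA:
        s += gamma * fr.f_free
    return s


class FitnessDecomposition:
    """Model object solving alpha/beta/gamma from per-medium S values.

    Parameters
    ----------
    s_by_medium : mapping of Medium -> S (per hour)
        Must contain PLUS_URA (anchors alpha); MINUS_URA and FOA are
        optional and yield beta/gamma when present.
    fractions : PopulationFractions
        Protein partition of the environment, shared across media.
    env_label : str, optional
    """

    def __init__(self, s_by_medium, fractions: PopulationFractions,
                 env_label: str = ""):
        self.s_by_medium = {Medium.parse(k): float(v) for k, v in s_by_medium.items()}
        if Medium.PLUS_URA not in self.s_by_medium:
            raise ValueError("PLUS_URA selection coefficient is required to anchor alpha")
        self.fractions = fractions
        self.env_label = env_label

    @classmethod
    def from_cells(cls, s_by_medium, agg_cells: pd.DataFrame,
                   sol_cells: pd.DataFrame, env_label: str = "",
                   **fraction_kw) -> "FitnessDecomposition":
        fr = population_fractions(agg_cells, sol_cells, **fraction_kw)
        return cls(s_by_medium, fr, env_label=env_label)

    def fit(self) -> "DecompositionResults":
        fr = self.fractions
        alpha = estimate_alpha(self.s_by_medium[Medium.PLUS_URA], fr)
        beta = gamma = None
        if Medium.MINUS_URA in self.s_by_medium:
            beta = estimate_beta(self.s_by_medium[Medium.MINUS_URA], alpha, fr)
        if Medium.FOA in self.s_by_medium:
            gamma = estimate_gamma(self.s_by_medium[Medium.FOA], alpha, fr)
        return DecompositionResults(alpha=alpha, beta=beta, gamma=gamma,
                                    fractions=fr, env_label=self.env_label,
                                    s_observed=dict(self.s_by_medium))


@dataclass
class DecompositionResults:
    """Fitted cost/benefit magnitudes for one environment (per hour)."""

    alpha: float
    beta: float | None
    gamma: float | None
    fractions: PopulationFractions
    env_label: str = ""
    s_observed: dict = field(default_factory=dict)

    def predict(self, medium: "Medium | str") -> float:
        return predict_S(self.alpha, self.beta or 0.0, self.gamma or 0.0,
                         self.fractions, medium)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for medium, s_obs in self.s_observed.items():
            rows.append({
                "env": self.env_label,
                "medium": medium.name,
                "S_observed": s_obs,
                "S_predicted": self.predict(medium),
                "alpha": self.alpha,
                "beta": self.beta,
                "gamma": self.gamma,
                "f_foci": self.fractions.f_foci,
                "f_free": self.fractions.f_free,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        fr = self.fractions
        fmt = lambda v: "      --" if v is None else f"{v:>8.4f}"
        lines = [
            f"Fitness decomposition{'  [' + self.env_label + ']' if self.env_label else ''}",
            "---------------------------------------------",
            f"f_foci (deposited fraction)        {fr.f_foci:>8.4f}",
            f"f_free (apparent free fraction)    {fr.f_free:>8.4f}",
            f"alpha  (deposit cost, 1/h)         {fmt(self.alpha)}",
            f"beta   (loss-of-function, 1/h)     {fmt(self.beta)}",
            f"gamma  (gain-of-protection, 1/h)   {fmt(self.gamma)}",
        ]
        for medium, s_obs in self.s_observed.items():
            lines.append(
                f"S[{medium.name:<9}] observed {s_obs:>8.4f}  predicted {self.predict(medium):>8.4f}"
            )
        return "\n".join(lines)
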