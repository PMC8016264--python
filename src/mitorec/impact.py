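"""Zygote-to-gamete transmission-impact model for conversion and crossover.

A mitotic conversion enters one of two daughter cells, so each of the ``n``
divisions on the zygote-to-gamete path contributes ``R_mi(GC)/2`` heritable
events; weighting by the mean tract length gives the expected number of
base pairs converted on that path per generation:

    E_mi(GC) = sum_{i=1..n} (1/2) R_mi(GC) L_mi(GC) = n/2 * R_mi(GC) * L_mi(GC)

There is a single meiosis per generation and a meiotic conversion reaches
any given gamete with probability 1/4:

    E_me(GC) = (1/4) R_me(GC) L_me(GC)

For yeast the meiotic side is expressed through the fraction of markers
converted per meiosis (CM_me) and the marker spacing (MD_me), with the same
1/4 transmission factor: E_me = (1/4) CM_me MD_me.  Crossovers compare by
event probability alone: P_mi(CO) = n/2 * R_mi(CO) against the per-
generation meiotic value P_me(CO).

Rates are treated as division-independent (the homogeneity assumption);
the summation API accepts a per-division rate vector so that assumption is
relaxable without an API change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImpactParams",
    "YeastParams",
    "RICE_R_MI_GC",
    "RICE_R_MI_CO",
    "R_ME_GC_RICE",
    "P_ME_CO_RICE",
    "L_MI_GC_BP",
    "L_ME_GC_BP",
    "YEAST",
    "PRESETS",
    "e_mi_gc",
    "e_me_gc",
    "p_mi_co",
    "co_transmission_ratio",
    "parity_divisions",
    "impact_curve",
]

#: per-mitosis conversion rates calibrated under the four founder
#: configurations (per marker pair per division)
RICE_R_MI_GC: tuple[float, ...] = (4.63e-6, 8.92e-6, 5.20e-6, 1.68e-5)
#: per-mitosis crossover rates under the same four configurations
RICE_R_MI_CO: tuple[float, ...] = (1.46e-5, 2.82e-5, 1.64e-5, 5.32e-5)

#: per-meiosis conversion rate at the locus: 24 events in 18,000
#: individuals, two meioses per individual, 1/4 transmission per gamete
R_ME_GC_RICE: float = 24 / 18_000 / 2 / 0.25
#: per-generation meiotic CO transmission probability: 26 events, same scheme
P_ME_CO_RICE: float = 26 / 18_000 / 2 / 0.25

#: mean mitotic conversion tract (bp), marker-based midpoint estimate
L_MI_GC_BP: float = 50_297.08
#: mean meiotic conversion tract (bp), same marker set
L_ME_GC_BP: float = 9_755.5

#: alternative tract means: whole-genome-refined mitotic mean, per-event
#: summed mitotic mean, and the refined meiotic mean
L_MI_GC_REFINED_BP: float = 28_500.0
L_MI_GC_PER_EVENT_BP: float = 40_500.0
L_ME_GC_REFINED_BP: float = 3_121.0


@dataclass(frozen=True)
class ImpactParams:
    """Full symbol set of the impact comparison."""

    r_mi_gc: float
    l_mi_gc: float
    r_me_gc: float
    l_me_gc: float
    r_mi_co: float = 0.0
    p_me_co: float = P_ME_CO_RICE
    n_divisions: int = 40

    def __post_init__(self) -> None:
        for r in (self.r_mi_gc, self.r_me_gc, self.r_mi_co, self.p_me_co):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.l_mi_gc <= 0 or self.l_me_gc <= 0:
            raise ValueError("tract lengths must be positive")
        if self.n_divisions < 0:
            raise ValueError("n_divisions must be non-negative")


@dataclass(frozen=True)
class YeastParams:
    """Yeast parameterisation: mitotic rate/tract plus the meiotic
    converted-marker fraction and marker spacing."""

    rate_per_division: float = 1.3e-6
    l_mi: float = 30_790.0
    cm_me: float = 0.02
    md_me: float = 227.0

    def e_me(self) -> float:
        return 0.25 * self.cm_me * self.md_me


YEAST = YeastParams()


def e_mi_gc(
    n: int,
    r_mi_gc: float | Sequence[float],
    l_mi_gc: float,
) -> float:
    """Expected bp converted on the zygote-to-gamete path by mitotic GC.

    ``r_mi_gc`` may be a scalar (constant-rate closed form n/2*R*L) or a
    length-``n`` per-division rate vector (explicit summation).
    """
    if l_mi_gc <= 0:
        raise ValueError("tract length must be positive")
    if np.ndim(r_mi_gc) == 0:
        if n < 0:
            raise ValueError("n must be non-negative")
        return n * 0.5 * float(r_mi_gc) * l_mi_gc
    rates = np.asarray(r_mi_gc, dtype=float)
    if len(rates) != n:
        raise ValueError("per-division rate vector must have length n")
    return float(np.sum(0.5 * rates * l_mi_gc))


def e_me_gc(r_me_gc: float, l_me_gc: float) -> float:
    """Expected bp converted in a gamete by the single meiosis: R*L/4.

    The yeast form is the same expression with the converted-marker
    fraction and marker distance: e_me_gc(CM_me, MD_me).
    """
    return 0.25 * r_me_gc * l_me_gc


def p_mi_co(n: int, r_mi_co: float | Sequence[float]) -> float:
    """Probability a mitotic CO is carried by the pregametic cell: n/2*R."""
    if np.ndim(r_mi_co) == 0:
        if n < 0:
            raise ValueError("n must be non-negative")
        return n * 0.5 * float(r_mi_co)
    rates = np.asarray(r_mi_co, dtype=float)
    if len(rates) != n:
        raise ValueError("per-division rate vector must have length n")
    return float(np.sum(0.5 * rates))


def co_transmission_ratio(n: int, r_mi_co: float, p_me_co: float = P_ME_CO_RICE) -> float:
    """Mitotic-to-meiotic CO transmission ratio at n divisions."""
    if p_me_co <= 0:
        raise ValueError("meiotic CO probability must be positive")
    return p_mi_co(n, r_mi_co) / p_me_co


def parity_divisions(
    r_mi_gc: float, l_mi_gc: float, e_me: float
) -> tuple[int, int]:
    """Division counts bracketing mitotic/meiotic conversion parity.

    Returns ``(n_below, n_cross)``: the largest integer n with
    E_mi(n) < E_me and the first n with E_mi(n) >= E_me.
    """
    per_division = 0.5 * r_mi_gc * l_mi_gc
    if per_division <= 0:
        raise ValueError("mitotic per-division impact must be positive")
    if e_me <= 0:
        raise ValueError("meiotic impact must be positive")
    n_cross = math.ceil(e_me / per_division)
    return n_cross - 1, n_cross


def parity_divisions_yeast(params: YeastParams = YEAST) -> tuple[int, int]:
    return parity_divisions(params.rate_per_division, params.l_mi, params.e_me())


#: Named situations for the impact curves: {situation label: (R_mi(GC), L_mi, E_me)}
def _rice_situations(l_mi: float, l_me: float) -> dict[str, tuple[float, float, float]]:
    e_me = e_me_gc(R_ME_GC_RICE, l_me)
    return {
        f"situation_{i + 1}": (r, l_mi, e_me) for i, r in enumerate(RICE_R_MI_GC)
    }


PRESETS: dict[str, dict[str, tuple[float, float, float]]] = {
    # rice rates, marker-based tract means
    "rice-marker-tracts": _rice_situations(L_MI_GC_BP, L_ME_GC_BP),
    # rice rates, refined mitotic tract mean, marker-based meiotic mean
    "rice-refined-tracts": _rice_situations(L_MI_GC_REFINED_BP, L_ME_GC_BP),
    # rice rates, refined tract means on both sides
    "rice-refined-both": _rice_situations(L_MI_GC_REFINED_BP, L_ME_GC_REFINED_BP),
    # rice rates with yeast tract sizes (yeast meiotic tract mean ~2 kb)
    "rice-yeast-tracts": _rice_situations(YEAST.l_mi, 2_000.0),
    # yeast rates and tract sizes
    "yeast": {"yeast": (YEAST.rate_per_division, YEAST.l_mi, YEAST.e_me())},
}


def impact_curve(
    n_max: int = 100,
    situations: Mapping[str, tuple[float, float, float]] | None = None,
    preset: str | None = None,
) -> pd.DataFrame:
    """Tabulate E_mi(n), E_me and their ratio for n = 1..n_max.

    ``situations`` maps a label to ``(r_mi_gc, l_mi_gc, e_me)``; or pass a
    ``preset`` name from :data:`PRESETS`.  Returns a long DataFrame with
    columns (situation, n, E_mi_bp, E_me_bp, ratio).
    """
    if situations is None:
        if preset is None:
            preset = "rice-marker-tracts"
        try:
            situations = PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rows = []
    for label, (r_mi, l_mi, e_me) in situations.items():
        for n in range(1, n_max + 1):
            emi = e_mi_gc(n, r_mi, l_mi)
            rows.append(
                {
                    "situation": label,
                    "n": n,
                    "E_mi_bp": emi,
                    "E_me_bp": e_me,
                    "ratio": emi / e_me,
                }
            )
    return pd.DataFrame(rows)


def plot_impact_curve(curve: pd.DataFrame, path: str) -> None:
    """Plot E_mi(n) against the constant E_me per situation (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sub in curve.groupby("situation"):
        ax.plot(sub["n"], sub["E_mi_bp"], label=f"{label} E_mi")
        ax.axhline(sub["E_me_bp"].iloc[0], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("cell divisions zygote → gamete (n)")
    ax.set_ylabel("expected bp converted per generation")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
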