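"""Grid search of the fitness landscape over prey-preference space.

Both fitness functionals — life reproductive success X and reproductive-season
growth Z — are evaluated on a uniform grid {i/(n-1)}^2 over (P_A, P_B).
Surfaces in this model can be strongly non-concave (the benefit of cannibalism
trades off against lineage elimination and time delay), so an exhaustive sweep
is used rather than a gradient method; at desk scale it costs seconds.  Ties
are broken toward the smallest P_A, then the smallest P_B.
"""

from __future__ import annotations

from dataclasses import dataclass

import json

import numpy as np
import pandas as pd

from . import foraging
from .lineage import _founders_arrays, _season_census_arrays
from .params import ForagingParameters, LifeHistoryConfig, PreyPreference
from .territory import _run_schedule_arrays

FITNESS_KINDS = ("X", "Z")


@dataclass(frozen=True)
class FitnessSurface:
    """A fitness landscape over the preference grid, with its argmax."""

    kind: str
    grid: np.ndarray          # the shared axis, grid[i] = i/(n-1)
    values: np.ndarray        # values[i, j] = fitness(P_A=grid[i], P_B=grid[j])
    argmax_p_a: float
    argmax_p_b: float
    max_value: float

    def __post_init__(self):
        if self.kind not in FITNESS_KINDS:
            raise ValueError(f"fitness kind must be one of {FITNESS_KINDS}, got {self.kind!r}")
        if not np.isclose(self.max_value, self.values.max(), rtol=1e-12):
            raise ValueError("argmax value inconsistent with surface maximum")

    def to_frame(self) -> pd.DataFrame:
        n = self.grid.size
        return pd.DataFrame({
            "p_a": np.repeat(self.grid, n),
            "p_b": np.tile(self.grid, n),
            "fitness": self.values.ravel(),
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def argmax_dict(self) -> dict:
        return {"kind": self.kind, "p_a": self.argmax_p_a,
                "p_b": self.argmax_p_b, "max": self.max_value}

    def argmax_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.argmax_dict(), fh, indent=2)
            fh.write("\n")

    def plot(self, ax=None):
        """Heat map of the surface (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.values.T, origin="lower", extent=(0, 1, 0, 1),
                       aspect="auto", cmap="viridis")
        ax.plot(self.argmax_p_a, self.argmax_p_b, "r*", markersize=10)
        ax.set_xlabel("conspecific preference $P_A$")
        ax.set_ylabel("heterospecific preference $P_B$")
        ax.set_title(f"{self.kind} fitness surface")
        plt.colorbar(im, ax=ax, label=self.kind)
        return ax


def fitness_surface(kind: str, fp: ForagingParameters, lh: LifeHistoryConfig,
                    grid_n: int = 100,
                    substeps: int = foraging.DEFAULT_SUBSTEPS) -> FitnessSurface:
    """Evaluate X or Z on the uniform grid and locate its maximum."""
    if kind not in FITNESS_KINDS:
        raise ValueError(f"fitness kind must be one of {FITNESS_KINDS}, got {kind!r}")
    if grid_n < 2:
        raise ValueError(f"grid_n must be >= 2, got {grid_n}")
    g = np.linspace(0.0, 1.0, grid_n)
    p_a = np.repeat(g, grid_n)
    p_b = np.tile(g, grid_n)
    out = _run_schedule_arrays(p_a, p_b, fp, lh, substeps)
    if kind == "X":
        flat = out["a"].sum(axis=0)
    else:
        f = _founders_arrays(out["a"], lh)
        flat = _season_census_arrays(f, out["census_hatched"], lh)
    values = flat.reshape(grid_n, grid_n)
    # np.argmax returns the first flat maximum; with P_A on the slow axis this
    # realizes the smallest-P_A-then-smallest-P_B tie-break.
    i = int(np.argmax(values))
    ia, ib = divmod(i, grid_n)
    return FitnessSurface(kind=kind, grid=g, values=values,
                          argmax_p_a=float(g[ia]), argmax_p_b=float(g[ib]),
                          max_value=float(values[ia, ib]))


def compare_fitness_optima(fp: ForagingParameters, lh: LifeHistoryConfig,
                           grid_n: int = 100,
                           substeps: int = foraging.DEFAULT_SUBSTEPS) -> dict:
    """Optimal foraging strategies under both fitness definitions.

    Returns a dict with the argmax preference and maximum of each surface —
    the comparison that decides whether cannibalism optimal for life
    reproductive success is also optimal for season-end descendant numbers.
    """
    sx = fitness_surface("X", fp, lh, grid_n, substeps)
    sz = fitness_surface("Z", fp, lh, grid_n, substeps)
    return {
        "argmax_X": PreyPreference(sx.argmax_p_a, sx.argmax_p_b),
        "max_X": sx.max_value,
        "argmax_Z": PreyPreference(sz.argmax_p_a, sz.argmax_p_b),
        "max_Z": sz.max_value,
    }
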