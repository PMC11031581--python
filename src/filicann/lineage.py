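"""Reproductive-season growth of a founding female's lineage.

Every female in the lineage shares the focal phenotype and an identical,
time-shifted territory schedule, because the heterospecific prey supply is the
same in every territory.  The descendants tree therefore collapses to a
renewal recursion on founder counts: with ``a(tau)`` the adult daughters
produced from eggs laid at maternal age tau, and ``d = maturation_units +
migration_units`` the lag from laying to founding one's own territory,

    f(1) = 1   (Eve founds her territory at step 1)
    f(t) = sum_tau f(t - tau - d) * a(tau)

The season growth rate Z counts the descendants of Eve alive at the end of
step ``season_units``: in every founded territory the post-cannibalism nymph
cohorts, the daughters in their migration step and the founding female while
she lives.  Unhatched egg cohorts are not counted (Z counts hatched
individuals; the production schedule is itself expressed in hatched-nymph
equivalents).  Eve herself is excluded — Z is the number of her descendants.
Lineages founded near the season's end contribute truncated schedules.

The explicit generation-by-generation tree expansion
(:func:`descendants_tree_census`) is mathematically equivalent and kept as an
independent cross-check of the renewal shortcut.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import foraging
from .params import ForagingParameters, LifeHistoryConfig, PreyPreference
from .territory import _run_schedule_arrays


def _founders_arrays(a: np.ndarray, lh: LifeHistoryConfig) -> np.ndarray:
    """Renewal recursion for founder counts, vectorized over grid points.

    ``a`` has shape (L+1, G); returns ``f`` of shape (S+1, G) with ``f[t]``
    the expected number of territories founded at step t.
    """
    L = lh.maternal_reproductive_units
    S = lh.season_units
    d = lh.founding_lag
    G = a.shape[1]
    f = np.zeros((S + 1, G))
    f[1] = 1.0
    for t in range(2, S + 1):
        for tau in range(1, L + 1):
            s = t - tau - d
            if s >= 1:
                f[t] += f[s] * a[tau]
    return f


def _season_census_arrays(f: np.ndarray, census: np.ndarray,
                          lh: LifeHistoryConfig) -> np.ndarray:
    """Total living descendants of Eve at the end of the season (grid arrays)."""
    S = lh.season_units
    span = census.shape[0] - 2
    Z = np.zeros(f.shape[1])
    for s in range(1, S + 1):
        u = S - s + 1
        if u <= span:
            Z += f[s] * census[u]
    if S <= lh.maternal_reproductive_units:
        Z -= 1.0  # Eve still alive: she is counted in her own territory's census
    return Z


def season_growth(pref: PreyPreference, fp: ForagingParameters,
                  lh: LifeHistoryConfig,
                  substeps: int = foraging.DEFAULT_SUBSTEPS,
                  include_eggs: bool = False) -> float:
    """Number of Eve's descendants alive at the end of the reproductive season.

    ``include_eggs`` adds the unhatched egg cohorts to the count; the default
    convention counts hatched individuals only.
    """
    out = _run_schedule_arrays(pref.p_a, pref.p_b, fp, lh, substeps)
    f = _founders_arrays(out["a"], lh)
    census = out["census_hatched"]
    if include_eggs:
        census = census + out["census_eggs"]
    return float(_season_census_arrays(f, census, lh)[0])


def lineage_trace(pref: PreyPreference, fp: ForagingParameters,
                  lh: LifeHistoryConfig,
                  substeps: int = foraging.DEFAULT_SUBSTEPS) -> pd.DataFrame:
    """Per-step founder counts and total living descendants (diagnostic view).

    Columns: ``step``, ``founders`` (territories founded that step),
    ``population`` (living descendants of Eve at the end of that step).
    """
    out = _run_schedule_arrays(pref.p_a, pref.p_b, fp, lh, substeps)
    f = _founders_arrays(out["a"], lh)
    census = out["census_hatched"]
    span = census.shape[0] - 2
    S = lh.season_units
    L = lh.maternal_reproductive_units
    rows = []
    for t in range(1, S + 1):
        pop = 0.0
        for s in range(1, t + 1):
            u = t - s + 1
            if u <= span:
                pop += float(f[s, 0] * census[u, 0])
        if t <= L:
            pop -= 1.0  # Eve
        rows.append({"step": t, "founders": float(f[t, 0]), "population": pop})
    return pd.DataFrame(rows)


def descendants_tree_census(pref: PreyPreference, fp: ForagingParameters,
                            lh: LifeHistoryConfig,
                            substeps: int = foraging.DEFAULT_SUBSTEPS,
                            include_eggs: bool = False) -> float:
    """Season growth by explicit expansion of the descendants tree.

    Generation by generation: Eve founds at step 1; every founder's daughters
    found their own territories ``tau + founding_lag`` steps later, carrying
    real-valued multiplicities.  Independent cross-check of
    :func:`season_growth` (which uses the renewal convolution instead).
    """
    out = _run_schedule_arrays(pref.p_a, pref.p_b, fp, lh, substeps)
    a = out["a"][:, 0]
    census = out["census_hatched"][:, 0]
    if include_eggs:
        census = census + out["census_eggs"][:, 0]
    L = lh.maternal_reproductive_units
    S = lh.season_units
    d = lh.founding_lag
    span = census.shape[0] - 2
    generation = {1: 1.0}
    Z = 0.0
    while generation:
        nxt: dict[int, float] = {}
        for s, count in generation.items():
            u = S - s + 1
            if u <= span:
                Z += count * census[u]
            for tau in range(1, L + 1):
                t = s + tau + d
                if t <= S and a[tau] > 0:
                    nxt[t] = nxt.get(t, 0.0) + count * a[tau]
        generation = nxt
    if S <= lh.maternal_reproductive_units:
        Z -= 1.0
    return float(Z)
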