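"""Single-territory recursion: one focal female from first egg to last daughter.

Within-step event order is forage -> remove consumed nymphs -> lay newly
produced eggs -> advance every cohort one stage.  Eggs laid at maternal age
tau hatch ``egg_units`` steps later, pass through the three cannibalizable
nymph classes, and the survivors leave the territory as young adult females
``maturation_units`` steps after laying.  While the mother lives (the first
``maternal_reproductive_units`` = L steps) she forages on her own nymphs and
on the constant heterospecific supply; after her death the remaining cohorts
develop and leave unharmed.  The schedule therefore spans
``L + maturation_units`` steps.

The engine is vectorized over preference points: every public function accepts
scalars, and the private ``_run_schedule_arrays`` runs whole preference grids
at once for the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import foraging
from .params import ForagingParameters, LifeHistoryConfig, PreyPreference


def _run_schedule_arrays(p_a, p_b, fp: ForagingParameters, lh: LifeHistoryConfig,
                         substeps: int = foraging.DEFAULT_SUBSTEPS) -> dict:
    """Run the territory recursion for arrays of preference points.

    Returns a dict of arrays indexed by maternal laying age tau (axis 0,
    entry 0 unused) and grid point (axis 1):

    ``e``        hatched-nymph equivalents laid at age tau
    ``a``        adult daughters from age-tau eggs that leave the territory
    ``consumed`` per-step consumption (cohorts 3/4/5 and heterospecific)
    ``census_hatched``  individuals present in/around the territory at the
                 end of local step u: post-cannibalism nymph cohorts, the
                 daughters in their migration step, and the mother while she
                 lives (entry [u] for u = 1..span)
    ``census_eggs``     unhatched egg-cohort counts at the end of step u
    """
    p_a = np.atleast_1d(np.asarray(p_a, dtype=float))
    p_b = np.atleast_1d(np.asarray(p_b, dtype=float))
    p_a, p_b = np.broadcast_arrays(p_a, p_b)
    G = p_a.shape[0]
    L = lh.maternal_reproductive_units
    E = lh.egg_units
    nsu = lh.nymph_stage_units
    T = float(lh.activity_minutes_per_unit)
    span = L + lh.maturation_units

    e = np.zeros((L + 1, G))
    surv: dict[int, np.ndarray] = {}
    cons = {key: np.zeros((L + 1, G)) for key in ("c3", "c4", "c5", "het")}
    census_h = np.zeros((span + 2, G))
    census_e = np.zeros((span + 2, G))

    def class_members(t: int, j: int) -> list[int]:
        """Laying ages whose cohort is in cannibalizable class j (1..3) at step t."""
        lo = t - (E + j * nsu - 1)
        hi = t - (E + (j - 1) * nsu)
        return [tau for tau in range(max(lo, 1), min(hi, L) + 1)]

    for t in range(1, span + 1):
        if t <= L:
            members = [class_members(t, j) for j in (1, 2, 3)]
            totals = [sum((surv[tau] for tau in m), np.zeros(G)) for m in members]
            rem3, rem4, rem5, het = foraging.integrate_consumption(
                totals[0], totals[1], totals[2], fp.y, p_a, p_b, fp, T, substeps)
            remaining = [rem3, rem4, rem5]
            for j, (m, before, after) in enumerate(zip(members, totals, remaining)):
                cons[("c3", "c4", "c5")[j]][t] = before - after
                frac = np.where(before > 0, after / np.where(before > 0, before, 1.0), 1.0)
                for tau in m:
                    surv[tau] = surv[tau] * frac
            cons["het"][t] = het
            e[t] = (fp.a3 * cons["c3"][t] + fp.a4 * cons["c4"][t]
                    + fp.a5 * cons["c5"][t] + fp.b * het)
            surv[t] = e[t].copy()
        # end-of-step census
        for tau in range(1, min(t, L) + 1):
            age = t - tau  # 0-based steps since laying
            if age < E:
                census_e[t] += surv[tau] if tau in surv else 0.0
            elif age < E + 3 * nsu:
                census_h[t] += surv[tau]
        if t <= L:
            census_h[t] += 1.0  # the mother herself
        leave_age = lh.maturation_units
        tau_leaving = t - leave_age
        if 1 <= tau_leaving <= L:
            census_h[t] += surv[tau_leaving]  # daughters in their migration step

    a = np.zeros((L + 1, G))
    for tau in range(1, L + 1):
        a[tau] = surv[tau]
    return {"e": e, "a": a, "consumed": cons,
            "census_hatched": census_h, "census_eggs": census_e, "span": span}


@dataclass
class TerritorySchedule:
    """Complete bookkeeping of one focal female's territory."""

    pref: PreyPreference
    fp: ForagingParameters
    lh: LifeHistoryConfig
    e: np.ndarray            # hatched-nymph equivalents laid at age tau (index tau)
    a: np.ndarray            # adult daughters leaving, by laying age tau
    consumed_c3: np.ndarray  # per-step consumption records (index = step)
    consumed_c4: np.ndarray
    consumed_c5: np.ndarray
    consumed_het: np.ndarray
    census_hatched: np.ndarray = field(repr=False)
    census_eggs: np.ndarray = field(repr=False)
    span: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-step table mirroring the biological scheme's layout."""
        L = self.lh.maternal_reproductive_units
        E = self.lh.egg_units
        nsu = self.lh.nymph_stage_units
        rows = []
        remaining = {tau: float(self.e[tau]) for tau in range(1, L + 1)}
        # replay cannibalism losses to tabulate per-step cohort counts
        eaten = {t: (self.consumed_c3[t], self.consumed_c4[t], self.consumed_c5[t])
                 for t in range(1, L + 1)}
        for t in range(1, self.span + 1):
            counts = {f"c{i}": 0.0 for i in range(1, 7)}
            if t <= L:
                for j in (1, 2, 3):
                    members = [tau for tau in range(1, L + 1)
                               if E + (j - 1) * nsu <= t - tau <= E + j * nsu - 1]
                    tot = sum(remaining[tau] for tau in members)
                    loss = eaten[t][j - 1]
                    frac = (tot - loss) / tot if tot > 0 else 1.0
                    for tau in members:
                        remaining[tau] *= frac
            for tau in range(1, min(t, L) + 1):
                age = t - tau
                if age < E:
                    counts[f"c{min(age + 1, 2)}"] += float(self.e[tau])
                elif age < E + 3 * nsu:
                    j = (age - E) // nsu + 1
                    counts[f"c{j + 2}"] += remaining[tau]
                elif age == E + 3 * nsu:
                    counts["c6"] += remaining[tau]
            rows.append({
                "step": t,
                "age": t if t <= L else 0,
                "e": float(self.e[t]) if t <= L else 0.0,
                **counts,
                "consumed_c3": float(self.consumed_c3[t]) if t <= L else 0.0,
                "consumed_c4": float(self.consumed_c4[t]) if t <= L else 0.0,
                "consumed_c5": float(self.consumed_c5[t]) if t <= L else 0.0,
                "consumed_het": float(self.consumed_het[t]) if t <= L else 0.0,
                "a": float(self.a[t - self.lh.maturation_units])
                if 1 <= t - self.lh.maturation_units <= L else 0.0,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_focal_female(pref: PreyPreference, fp: ForagingParameters,
                     lh: LifeHistoryConfig,
                     substeps: int = foraging.DEFAULT_SUBSTEPS) -> TerritorySchedule:
    """Run the recursion for a single preference point."""
    out = _run_schedule_arrays(pref.p_a, pref.p_b, fp, lh, substeps)
    L = lh.maternal_reproductive_units
    sq = lambda arr: arr[:, 0].copy()
    return TerritorySchedule(
        pref=pref, fp=fp, lh=lh,
        e=sq(out["e"]), a=sq(out["a"]),
        consumed_c3=sq(out["consumed"]["c3"]),
        consumed_c4=sq(out["consumed"]["c4"]),
        consumed_c5=sq(out["consumed"]["c5"]),
        consumed_het=sq(out["consumed"]["het"]),
        census_hatched=sq(out["census_hatched"]),
        census_eggs=sq(out["census_eggs"]),
        span=out["span"],
    )


def life_reproductive_success(sched: TerritorySchedule) -> float:
    """Life reproductive success X: all adult daughters that leave the
    territory over the mother's life."""
    return float(sched.a.sum())
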