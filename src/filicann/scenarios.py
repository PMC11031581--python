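"""Seeded scenario generation and individual-based verification oracles.

The deterministic recursion tracks expected values.  The oracles here
re-derive those expectations from explicitly stochastic simulations — integer
individuals, sequential search-and-handling foraging bouts, Bernoulli attacks
and successes, Poisson offspring — so that agreement is an independent check
of the recursion's arithmetic rather than a re-run of it.  The law of large
numbers makes the comparison meaningful in regimes where prey counts are
large relative to one female's consumption (weak within-step nonlinearity);
the default random scenarios are drawn accordingly for the territory oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .foraging import ConsumptionRecord
from .params import (CohortState, ForagingParameters, LifeHistoryConfig,
                     ParameterError, PreyPreference, validate_parameters)

_DEFAULT_RANGES = {
    "y": (1.0, 50.0),
    "b": (0.01, 2.0),
    "tau_a": (1.0, 120.0),
    "tau_b": (1.0, 120.0),
    "tau_s": (1.0, 120.0),
    "k": (0.1, 1.0),
    "a": (0.1, 15.0),
}


def random_parameters(seed: int, ranges: dict | None = None
                      ) -> tuple[ForagingParameters, LifeHistoryConfig]:
    """Reproducibly sample a structurally valid parameter set.

    Success probabilities are sorted so that ``k3 >= k4 >= k5`` (older, larger
    nymphs escape the maternal attack more often) and conversion coefficients
    so that ``a3 <= a4 <= a5`` (older nymphs carry more biomass), matching the
    orderings of the measured set.  ``ranges`` may override the sampling
    bounds per key of ``_DEFAULT_RANGES``.
    """
    bounds = dict(_DEFAULT_RANGES)
    if ranges:
        for key, val in ranges.items():
            if key not in bounds:
                raise ParameterError(key, "unknown range key")
            lo, hi = val
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ParameterError(key, f"malformed range {val!r}")
            bounds[key] = (float(lo), float(hi))
    rng = np.random.default_rng(seed)
    u = lambda key: float(rng.uniform(*bounds[key]))
    ks = np.sort(rng.uniform(*bounds["k"], size=3))[::-1]
    as_ = np.sort(rng.uniform(*bounds["a"], size=3))
    fp = ForagingParameters(
        y=u("y"), b=u("b"),
        tau_a=u("tau_a"), tau_b=u("tau_b"), tau_s=u("tau_s"),
        k3=float(ks[0]), k4=float(ks[1]), k5=float(ks[2]),
        a3=float(as_[0]), a4=float(as_[1]), a5=float(as_[2]),
    )
    lh = LifeHistoryConfig()
    return validate_parameters(fp, lh)


# ---------------------------------------------------------------------------
# stochastic foraging-bout oracle (fixed densities)

@dataclass(frozen=True)
class BoutOracleResult:
    mean: ConsumptionRecord
    se: ConsumptionRecord
    n_bouts: int


def simulate_functional_response(available, y, pref: PreyPreference,
                                 fp: ForagingParameters, T: float,
                                 n_bouts: int, seed: int) -> BoutOracleResult:
    """Monte-Carlo mean consumption over sequential foraging bouts.

    Search lasts ``tau_s`` minutes and ends with one prey item drawn by
    relative abundance; attacks are Bernoulli(preference), conspecific
    success Bernoulli(k_i); every attack pays its full handling time.
    Densities are held fixed within a bout (sampling with replacement), the
    stochastic counterpart of the single-cycle renewal form.
    """
    if isinstance(available, CohortState):
        c3, c4, c5 = available.nymphs
    else:
        c3, c4, c5 = available
    rng = np.random.default_rng(seed)
    x = c3 + c4 + c5
    tot = x + y
    counts = np.zeros((n_bouts, 4))
    ks = (fp.k3, fp.k4, fp.k5)
    taus = (fp.tau_a, fp.tau_a, fp.tau_a, fp.tau_b)
    for i in range(n_bouts):
        t = 0.0
        got = counts[i]
        if tot <= 0:
            continue
        while True:
            t += fp.tau_s
            if t >= T:
                break
            r = rng.uniform(0, tot)
            if r < x:  # conspecific encounter
                if r < c3:
                    j = 0
                elif r < c3 + c4:
                    j = 1
                else:
                    j = 2
                if rng.random() < pref.p_a:
                    t += fp.tau_a
                    if rng.random() < ks[j]:
                        got[j] += 1
            else:
                if rng.random() < pref.p_b:
                    t += fp.tau_b
                    got[3] += 1
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(n_bouts) if n_bouts > 1 else np.zeros(4)
    return BoutOracleResult(
        mean=ConsumptionRecord(*mean), se=ConsumptionRecord(*se), n_bouts=n_bouts)


# ---------------------------------------------------------------------------
# individual-based territory / lineage oracle

@dataclass(frozen=True)
class TerritoryOracleResult:
    e_mean: np.ndarray
    e_se: np.ndarray
    a_mean: np.ndarray
    a_se: np.ndarray
    z_mean: float | None
    z_se: float | None
    n_replicates: int


def _simulate_bout(nymphs: list[int], y: float, pref: PreyPreference,
                   fp: ForagingParameters, T: float, rng) -> tuple[list[int], int]:
    """One integer foraging bout with within-bout depletion of the brood.

    Returns consumed counts per nymph class and the number of heterospecific
    prey consumed.
    """
    consumed = [0, 0, 0]
    het = 0
    pool = list(nymphs)
    ks = (fp.k3, fp.k4, fp.k5)
    t = 0.0
    while True:
        t += fp.tau_s
        if t >= T:
            break
        x = pool[0] + pool[1] + pool[2]
        tot = x + y
        if tot <= 0:
            break
        r = rng.uniform(0, tot)
        if r < x:
            if r < pool[0]:
                j = 0
            elif r < pool[0] + pool[1]:
                j = 1
            else:
                j = 2
            if rng.random() < pref.p_a:
                t += fp.tau_a
                if rng.random() < ks[j]:
                    pool[j] -= 1
                    consumed[j] += 1
        else:
            if rng.random() < pref.p_b:
                t += fp.tau_b
                het += 1
    return consumed, het


def _simulate_territory(pref, fp, lh, rng):
    """One replicate of one female's territory with integer individuals.

    Offspring from each consumed item are Poisson with mean equal to the
    deterministic conversion coefficient, keeping expectations aligned with
    the recursion's arithmetic while remaining integer-valued.
    """
    L = lh.maternal_reproductive_units
    E = lh.egg_units
    nsu = lh.nymph_stage_units
    T = float(lh.activity_minutes_per_unit)
    cohorts = {}  # laying age -> remaining integer count
    e = np.zeros(L + 1)
    conv = (fp.a3, fp.a4, fp.a5)
    for t in range(1, L + 1):
        members = [[tau for tau in cohorts
                    if E + (j - 1) * nsu <= t - tau <= E + j * nsu - 1]
                   for j in (1, 2, 3)]
        pools = [sum(cohorts[tau] for tau in m) for m in members]
        consumed, het = _simulate_bout(pools, fp.y, pref, fp, T, rng)
        newborn = 0
        for j in range(3):
            # remove consumed[j] individuals uniformly among member cohorts
            for _ in range(consumed[j]):
                tot = sum(cohorts[tau] for tau in members[j])
                r = rng.uniform(0, tot)
                acc = 0
                for tau in members[j]:
                    acc += cohorts[tau]
                    if r < acc:
                        cohorts[tau] -= 1
                        break
            if conv[j] > 0 and consumed[j] > 0:
                newborn += rng.poisson(conv[j] * consumed[j])
        if fp.b > 0 and het > 0:
            newborn += rng.poisson(fp.b * het)
        e[t] = newborn
        cohorts[t] = newborn
    a = np.zeros(L + 1)
    for tau in range(1, L + 1):
        a[tau] = cohorts[tau]
    return e, a


def stochastic_oracle(pref: PreyPreference, fp: ForagingParameters,
                      lh: LifeHistoryConfig, n_replicates: int, seed: int,
                      simulate_season: bool = False,
                      population_cap: int = 1_000_000) -> TerritoryOracleResult:
    """Monte-Carlo means of e(tau), a(tau) — and optionally Z — from an
    individual-based simulation of the territory model.

    With ``simulate_season`` the whole descendants tree is simulated with
    integer individuals; intended for small parameter values only (a
    ``population_cap`` guards against exponential blow-up).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    L = lh.maternal_reproductive_units
    es = np.zeros((n_replicates, L + 1))
    as_ = np.zeros((n_replicates, L + 1))
    zs = np.zeros(n_replicates) if simulate_season else None
    for i in range(n_replicates):
        e, a = _simulate_territory(pref, fp, lh, rng)
        es[i] = e
        as_[i] = a
        if simulate_season:
            zs[i] = _simulate_season(pref, fp, lh, rng, population_cap)
    nsq = np.sqrt(n_replicates)
    se = lambda m: m.std(axis=0, ddof=1) / nsq if n_replicates > 1 else np.zeros(L + 1)
    return TerritoryOracleResult(
        e_mean=es.mean(axis=0), e_se=se(es),
        a_mean=as_.mean(axis=0), a_se=se(as_),
        z_mean=float(zs.mean()) if simulate_season else None,
        z_se=float(zs.std(ddof=1) / nsq) if simulate_season and n_replicates > 1 else None,
        n_replicates=n_replicates)


def _simulate_season(pref, fp, lh, rng, population_cap):
    """One stochastic replicate of Eve's whole lineage; returns the integer
    count of her living descendants at the season's end."""
    L = lh.maternal_reproductive_units
    E = lh.egg_units
    nsu = lh.nymph_stage_units
    S = lh.season_units
    d = lh.founding_lag
    mat = lh.maturation_units
    T = float(lh.activity_minutes_per_unit)
    conv = (fp.a3, fp.a4, fp.a5)
    # each territory: {"found": step, "cohorts": {laying_age: count}}
    territories = [{"found": 1, "cohorts": {}}]
    migrants_at_end = 0
    for t in range(1, S + 1):
        newcomers = []
        for terr in territories:
            age = t - terr["found"] + 1
            if age < 1:
                continue
            cohorts = terr["cohorts"]
            if age <= L:
                members = [[tau for tau in cohorts
                            if E + (j - 1) * nsu <= age - tau <= E + j * nsu - 1]
                           for j in (1, 2, 3)]
                pools = [sum(cohorts[tau] for tau in m) for m in members]
                consumed, het = _simulate_bout(pools, fp.y, pref, fp, T, rng)
                newborn = 0
                for j in range(3):
                    for _ in range(consumed[j]):
                        tot = sum(cohorts[tau] for tau in members[j])
                        r = rng.uniform(0, tot)
                        acc = 0
                        for tau in members[j]:
                            acc += cohorts[tau]
                            if r < acc:
                                cohorts[tau] -= 1
                                break
                    if conv[j] > 0 and consumed[j] > 0:
                        newborn += rng.poisson(conv[j] * consumed[j])
                if fp.b > 0 and het > 0:
                    newborn += rng.poisson(fp.b * het)
                cohorts[age] = newborn
            # daughters complete maturation during this step and depart;
            # each founds her own territory founding_lag steps after laying
            tau_leaving = age - mat
            if tau_leaving >= 1 and tau_leaving in cohorts:
                n_leave = cohorts.pop(tau_leaving)
                if t == S:
                    migrants_at_end += n_leave
                found_at = terr["found"] + tau_leaving + d
                if found_at <= S:
                    for _ in range(n_leave):
                        newcomers.append({"found": found_at, "cohorts": {}})
        territories.extend(newcomers)
        total = sum(sum(t_["cohorts"].values()) for t_ in territories)
        if total + len(territories) > population_cap:
            raise RuntimeError("population cap exceeded; use smaller parameters")
    # census at the end of step S: hatched nymphs, departing daughters,
    # founding females while alive; Eve (the first territory) excluded
    count = migrants_at_end
    for terr in territories:
        age = S - terr["found"] + 1
        for tau, n in terr["cohorts"].items():
            stage = age - tau
            if E <= stage < E + 3 * nsu and n > 0:
                count += n
        if terr["found"] > 1 and 1 <= age <= L:
            count += 1  # the founding female herself
    return count
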