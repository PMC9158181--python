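"""Monte-Carlo validity engine for the Sorensen equivalence tests.

Scenarios fix the number of terms n, the joint-enrichment law p (with
p11 usually derived from a target dissimilarity via the boundary solver),
the equivalence limit d0 and the level alpha; the engine estimates the
rejection probability of the chosen test flavour together with its
binomial Monte-Carlo standard error.  Placing the true dissimilarity at
d0 estimates the type-I error; below d0, power.

Two table generators are provided: a single multinomial draw of the
four cells, and a two-stage scheme that first draws the number of
enriched terms nu ~ Binomial(n, p11 + p01 + p10) and then splits it
multinomially among the three enriched cells.  Both induce the same law
on the table (property-tested), mirroring the two equivalent sampling
descriptions of the model.

Replicates whose table makes the studentized statistic undefined (zero
cells) are excluded and counted: with sparse enrichment the effective
replicate count can fall below the request.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bootstrap import equivalence_test_boot
from .contingency import EnrichmentContingencyTable, JointEnrichmentProbs
from .equivalence import p11_for_target
from .sorensen import (
    UndefinedSorensenError,
    _dissimilarity_array,
    _sigma_array,
    sorensen_dissimilarity,
)

__all__ = [
    "SimulationScenario",
    "SimulationResult",
    "generate_table",
    "generate_table_twostage",
    "run_scenario",
    "run_grid",
    "expand_grid",
    "synth_gene_lists",
]

#: simulation replicates for normal-test scenarios
DEFAULT_N_SIM = 100_000
#: (replicates, bootstrap size) for bootstrap scenarios
DEFAULT_BOOT_SIM = (2_000, 2_000)


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the validity-study grid."""

    n: int
    p: JointEnrichmentProbs
    d0: float
    alpha: float = 0.05
    n_sim: int = DEFAULT_N_SIM
    seed: int | None = None
    method: str = "normal"
    B: int = DEFAULT_BOOT_SIM[1]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.method not in ("normal", "bootstrap"):
            raise ValueError(f"method must be 'normal' or 'bootstrap': {self.method!r}")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")

    @property
    def dS_true(self) -> float:
        """Sorensen dissimilarity implied by the scenario's p."""
        return sorensen_dissimilarity(self.p)

    @property
    def expected_enriched(self) -> float:
        """E(nu) = n * (p11 + p01 + p10), the expected enriched-term count."""
        return self.n * self.p.enrichment_probability

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "p11": self.p.p11,
            "p01": self.p.p01,
            "p10": self.p.p10,
            "d0": self.d0,
            "alpha": self.alpha,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "method": self.method,
            "B": self.B,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationScenario":
        p = JointEnrichmentProbs(
            p11=payload["p11"], p01=payload["p01"], p10=payload["p10"]
        )
        kwargs = {k: payload[k] for k in ("alpha", "n_sim", "seed", "method", "B")
                  if k in payload}
        return cls(n=payload["n"], p=p, d0=payload["d0"], **kwargs)


@dataclass(frozen=True)
class SimulationResult:
    """Estimated rejection probability of one scenario."""

    scenario: SimulationScenario
    rejection_rate: float
    mc_se: float
    n_sim_effective: int
    coverage: float | None = None

    def to_dict(self) -> dict:
        out = self.scenario.to_dict()
        out.update(
            dS_true=self.scenario.dS_true,
            expected_enriched=self.scenario.expected_enriched,
            rejection_rate=self.rejection_rate,
            mc_se=self.mc_se,
            n_sim_effective=self.n_sim_effective,
            coverage=self.coverage,
        )
        return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_table(n: int, p: JointEnrichmentProbs, rng) -> EnrichmentContingencyTable:
    """One table from Multinomial(n, (p11, p01, p10, p00))."""
    rng = _as_rng(rng)
    n11, n01, n10, n00 = rng.multinomial(n, p.as_array())
    return EnrichmentContingencyTable(n11=n11, n10=n10, n01=n01, n00=n00)


def generate_table_twostage(
    n: int, p: JointEnrichmentProbs, rng
) -> EnrichmentContingencyTable:
    """Equivalent two-stage draw: nu ~ Bin(n, Pr{E}), then a conditional
    multinomial split of nu among the enriched cells."""
    rng = _as_rng(rng)
    pr_e = p.enrichment_probability
    if pr_e <= 0.0:
        raise ValueError("Pr{enriched} must be positive for the two-stage scheme")
    nu = int(rng.binomial(n, min(pr_e, 1.0)))
    pi = np.array([p.p11, p.p01, p.p10]) / pr_e
    if nu > 0:
        n11, n01, n10 = rng.multinomial(nu, pi)
    else:
        n11 = n01 = n10 = 0
    return EnrichmentContingencyTable(n11=n11, n10=n10, n01=n01, n00=n - nu)


def _run_normal_scenario(sc: SimulationScenario, rng) -> SimulationResult:
    # fully vectorized: all n_sim tables in one multinomial call
    draws = rng.multinomial(sc.n, sc.p.as_array(), size=sc.n_sim)
    n11, n01, n10 = draws[:, 0], draws[:, 1], draws[:, 2]
    d_hat = _dissimilarity_array(n11, n01, n10)
    sigma = _sigma_array(n11 / sc.n, n01 / sc.n, n10 / sc.n)
    valid = np.isfinite(d_hat) & np.isfinite(sigma) & (sigma > 0)
    n_eff = int(valid.sum())
    if n_eff == 0:
        raise UndefinedSorensenError(
            "no effective simulation replicates: enrichment too sparse"
        )
    d_hat, sigma = d_hat[valid], sigma[valid]
    t = math.sqrt(sc.n) * (d_hat - sc.d0) / sigma
    z_alpha = sps.norm.ppf(sc.alpha)
    rejections = t <= z_alpha
    rate = float(rejections.mean())
    z_up = sps.norm.ppf(1.0 - sc.alpha)
    d_upper = d_hat + z_up * sigma / math.sqrt(sc.n)
    coverage = float((sc.dS_true <= d_upper).mean())
    return SimulationResult(
        scenario=sc,
        rejection_rate=rate,
        mc_se=math.sqrt(rate * (1.0 - rate) / n_eff),
        n_sim_effective=n_eff,
        coverage=coverage,
    )


def _run_bootstrap_scenario(sc: SimulationScenario, rng) -> SimulationResult:
    rejections = 0
    covered = 0
    n_eff = 0
    for _ in range(sc.n_sim):
        table = generate_table(sc.n, sc.p, rng)
        try:
            res = equivalence_test_boot(table, sc.d0, sc.alpha, B=sc.B, seed=rng)
        except UndefinedSorensenError:
            continue
        n_eff += 1
        rejections += int(res.reject)
        covered += int(sc.dS_true <= res.d_upper)
    if n_eff == 0:
        raise UndefinedSorensenError(
            "no effective simulation replicates: enrichment too sparse"
        )
    rate = rejections / n_eff
    return SimulationResult(
        scenario=sc,
        rejection_rate=rate,
        mc_se=math.sqrt(rate * (1.0 - rate) / n_eff),
        n_sim_effective=n_eff,
        coverage=covered / n_eff,
    )


def run_scenario(scenario: SimulationScenario, rng=None) -> SimulationResult:
    """Estimate the rejection probability (and one-sided CI coverage) of
    one scenario; replicates with undefined statistics are excluded and
    reflected in ``n_sim_effective``."""
    rng = _as_rng(scenario.seed if rng is None else rng)
    if scenario.method == "normal":
        return _run_normal_scenario(scenario, rng)
    return _run_bootstrap_scenario(scenario, rng)


def run_grid(scenarios, master_seed: int | None = None) -> pd.DataFrame:
    """Run a list of scenarios; one tidy row per scenario.

    Each scenario gets an independent child RNG spawned deterministically
    from ``master_seed`` (scenario order does not couple the streams), so
    two runs with the same master seed produce identical tables.  Failed
    scenarios are recorded in an ``error`` column and the run continues.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("empty scenario grid")
    root = np.random.SeedSequence(master_seed)
    rows = []
    for i, sc in enumerate(scenarios):
        child = np.random.SeedSequence(
            master_seed if master_seed is not None else 0, spawn_key=(i,)
        ) if master_seed is not None else root.spawn(1)[0]
        rng = np.random.default_rng(child)
        row: dict = sc.to_dict()
        row["expected_enriched"] = sc.expected_enriched
        try:
            row["dS_true"] = sc.dS_true
            res = run_scenario(sc, rng=rng)
            row.update(
                rejection_rate=res.rejection_rate,
                mc_se=res.mc_se,
                n_sim_effective=res.n_sim_effective,
                coverage=res.coverage,
                error="",
            )
        except Exception as exc:  # keep the sweep alive, record the failure
            row.update(
                rejection_rate=np.nan,
                mc_se=np.nan,
                n_sim_effective=0,
                coverage=np.nan,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def expand_grid(
    d0_values,
    n_values,
    discordant_pairs,
    dS_values=None,
    alpha: float = 0.05,
    n_sim: int = DEFAULT_N_SIM,
    method: str = "normal",
    B: int = DEFAULT_BOOT_SIM[1],
) -> list[SimulationScenario]:
    """Cross d0, n and (p01, p10) levels into scenarios.

    For each (p01, p10) pair, p11 is derived from each target
    dissimilarity in ``dS_values`` (default: the boundary, dS = d0) via
    the boundary solver; infeasible combinations (probabilities summing
    above 1) are skipped.
    """
    scenarios = []
    for d0 in d0_values:
        targets = dS_values if dS_values is not None else [d0]
        for n in n_values:
            for p01, p10 in discordant_pairs:
                for dS in targets:
                    try:
                        p11 = p11_for_target(dS, p01, p10)
                        p = JointEnrichmentProbs(p11=p11, p01=p01, p10=p10)
                    except ValueError:
                        continue
                    scenarios.append(
                        SimulationScenario(
                            n=n, p=p, d0=d0, alpha=alpha, n_sim=n_sim,
                            method=method, B=B,
                        )
                    )
    return scenarios


def load_scenarios(path) -> list[SimulationScenario]:
    """Scenarios from a JSON file: an object or a list of objects."""
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, dict):
        payload = [payload]
    return [SimulationScenario.from_dict(item) for item in payload]


def synth_gene_lists(
    n_genes: int,
    n_terms: int,
    planted: tuple[int, int, int],
    effect_strength: float = 0.75,
    seed=None,
    list_size: int = 100,
    term_size: int = 20,
):
    """Synthetic gene lists + gene-set collection with a planted
    enrichment pattern, for end-to-end testing of the ORA front-end.

    ``planted = (k11, k10, k01)`` terms are constructed to be enriched in
    both lists, only in list 1, and only in list 2; the remaining terms
    draw their genes outside both lists and stay null.  A planted term
    takes ``round(effect_strength * term_size)`` of its genes from the
    target list(s) and fills up from genes outside both lists, so strong
    effects give overwhelming hypergeometric evidence.  Returns
    ``(lists, collection, universe, truth)`` with ``truth`` the planted
    incidence pattern keyed by term id.
    """
    from .enrichment import GeneSetCollection  # local import avoids a cycle

    k11, k10, k01 = planted
    if k11 + k10 + k01 > n_terms:
        raise ValueError("planted counts exceed the number of terms")
    rng = _as_rng(seed)
    universe = [f"g{i:05d}" for i in range(n_genes)]
    list1 = set(rng.choice(universe, size=list_size, replace=False))
    list2 = set(rng.choice(universe, size=list_size, replace=False))
    outside = sorted(set(universe) - list1 - list2)
    e = max(1, round(effect_strength * term_size))

    def _sample(pool, k):
        pool = sorted(pool)
        if k > len(pool):
            raise ValueError(
                "infeasible planting: not enough genes outside the lists "
                "to fill the term sets"
            )
        return set(rng.choice(pool, size=k, replace=False))

    sets, truth = {}, {}
    for t in range(n_terms):
        term = f"T{t:04d}"
        if t < k11:
            half = max(1, e // 2)
            genes = _sample(list1, half) | _sample(list2, half)
            genes |= _sample(set(outside) - genes, max(term_size - len(genes), 0))
            truth[term] = (1, 1)
        elif t < k11 + k10:
            genes = _sample(list1 - list2, e)
            genes |= _sample(set(outside) - genes, term_size - len(genes))
            truth[term] = (1, 0)
        elif t < k11 + k10 + k01:
            genes = _sample(list2 - list1, e)
            genes |= _sample(set(outside) - genes, term_size - len(genes))
            truth[term] = (0, 1)
        else:
            genes = _sample(outside, term_size)
            truth[term] = (0, 0)
        sets[term] = genes

    lists = {"list_1": list1, "list_2": list2}
    collection = GeneSetCollection(sets=sets)
    return lists, collection, frozenset(universe), truth
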