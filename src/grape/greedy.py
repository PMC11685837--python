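"""Greedy accumulation of stabilizing mutations over epistatic landscapes.

After single mutants are validated and clustered, combinations are built
within each cluster by steepest-ascent greedy search: each round evaluates
adding every remaining candidate to the current best variant and accepts
the best addition if it improves the measured ΔTm by at least the
acceptance tolerance (default 1.5 °C, the same bar used to call a single
mutant stabilizing). For a cluster of k candidates this costs at most
k + (k−1) + ... + 1 = k(k+1)/2 evaluations, a tiny fraction of the 2^k
combination space, which is the point: epistasis is explored where it
matters without exhaustive screening.

The synthetic :class:`EpistaticLandscape` stands in for wet-lab ΔTm
measurements: additive single-mutation effects plus pairwise epistatic
couplings on a random fraction of pairs, with optional Gaussian measurement
noise. :func:`brute_force_best` is the exact oracle used to quantify greedy
regret on small landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "EpistaticLandscape",
    "AccumulationPath",
    "simulate_landscape",
    "greedy_accumulate",
    "brute_force_best",
    "plan_experiment",
    "greedy_benchmark",
    "combine_cluster_winners",
]

DEFAULT_MIN_IMPROVEMENT = 1.5  # °C, the single-mutant stabilization bar


@dataclass
class EpistaticLandscape:
    """Ground-truth ΔTm over subsets of a mutation set.

    ΔTm(S) = Σ_{m∈S} a_m + Σ_{{m,n}⊆S} e_mn + ε,  ε ~ N(0, σ²) per call.
    """

    mutations: tuple[str, ...]
    additive: dict[str, float]
    epistasis: dict[frozenset, float]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self._rng = np.random.default_rng(self.seed)

    def true_value(self, subset) -> float:
        """Noise-free ΔTm of a subset."""
        s = set(subset)
        unknown = s - set(self.mutations)
        if unknown:
            raise KeyError(f"unknown mutations {sorted(unknown)}")
        # fixed summation order: reproducible across processes regardless of
        # set iteration (hash randomization)
        total = sum(self.additive[m] for m in sorted(s))
        total += sum(e for pair, e in sorted(self.epistasis.items(),
                                             key=lambda kv: sorted(kv[0]))
                     if pair <= s)
        return float(total)

    def measure(self, subset) -> float:
        """One noisy measurement of a subset's ΔTm."""
        value = self.true_value(subset)
        if self.noise_sd > 0:
            value += float(self._rng.normal(0.0, self.noise_sd))
        return value


def simulate_landscape(
    n: int,
    effect_distribution: tuple[float, float] = (1.0, 2.0),
    epistasis_fraction: float = 0.0,
    epistasis_sd: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    names: list[str] | None = None,
) -> EpistaticLandscape:
    """Draw a random landscape: additive effects ~ N(mean, sd²), pairwise
    couplings ~ N(0, epistasis_sd²) on a random ``epistasis_fraction`` of
    pairs. Reproducible for a seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= epistasis_fraction <= 1.0:
        raise ValueError("epistasis_fraction must be in [0, 1]")
    if epistasis_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"M{i + 1}" for i in range(n)]
    if len(names) != n:
        raise ValueError("names length must equal n")
    mean, sd = effect_distribution
    additive = {m: float(v) for m, v in zip(names, rng.normal(mean, sd, size=n))}
    pairs = list(combinations(names, 2))
    epistasis: dict[frozenset, float] = {}
    if pairs and epistasis_fraction > 0:
        n_epi = int(round(epistasis_fraction * len(pairs)))
        chosen = rng.choice(len(pairs), size=n_epi, replace=False)
        for idx in chosen:
            epistasis[frozenset(pairs[idx])] = float(rng.normal(0.0, epistasis_sd))
    return EpistaticLandscape(
        mutations=tuple(names), additive=additive, epistasis=epistasis,
        noise_sd=noise_sd, seed=seed,
    )


@dataclass
class AccumulationPath:
    """Record of one greedy run: accepted mutations in order, the measured
    ΔTm after each acceptance, every evaluation made, and why it stopped."""

    accepted: list[str] = field(default_factory=list)
    delta_tm_trace: list[float] = field(default_factory=list)
    evaluations: list[tuple[frozenset, float]] = field(default_factory=list)
    stop_reason: str = "no_improvement"

    @property
    def final_set(self) -> frozenset:
        return frozenset(self.accepted)

    @property
    def final_delta_tm(self) -> float:
        return self.delta_tm_trace[-1] if self.delta_tm_trace else 0.0

    @property
    def evaluations_used(self) -> int:
        return len(self.evaluations)


def greedy_accumulate(
    candidates: list[str],
    evaluate,
    start: str = "best_single",
    min_improvement: float = DEFAULT_MIN_IMPROVEMENT,
    budget: int | None = None,
) -> AccumulationPath:
    """Steepest-ascent accumulation over a candidate set.

    Round 1 measures every single mutant (``start="best_single"``) and
    accepts the best if it clears ``min_improvement`` over the wild type
    (ΔTm 0). Each later round measures the current accepted set plus each
    remaining candidate and accepts the best extension clearing the
    tolerance over the current measured value. Stops when no extension
    qualifies, candidates are exhausted, or the evaluation budget runs out.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if budget is not None and budget < 1:
        raise ValueError("budget must be >= 1")
    if start not in ("best_single", "empty"):
        raise ValueError("start must be 'best_single' or 'empty'")

    path = AccumulationPath()
    current: frozenset = frozenset()
    current_value = 0.0
    remaining = list(candidates)

    while remaining:
        round_results: list[tuple[str, float]] = []
        for cand in remaining:
            if budget is not None and path.evaluations_used >= budget:
                path.stop_reason = "budget"
                return path
            subset = current | {cand}
            try:
                value = float(evaluate(subset))
            except Exception as exc:
                path.stop_reason = "evaluator_error"
                exc.partial_path = path  # type: ignore[attr-defined]
                raise
            path.evaluations.append((subset, value))
            round_results.append((cand, value))
        best_cand, best_value = max(round_results, key=lambda cv: cv[1])
        if best_value >= current_value + min_improvement:
            current = current | {best_cand}
            current_value = best_value
            path.accepted.append(best_cand)
            path.delta_tm_trace.append(best_value)
            remaining.remove(best_cand)
        else:
            path.stop_reason = "no_improvement"
            return path
    path.stop_reason = "exhausted"
    return path


def brute_force_best(
    landscape: EpistaticLandscape, max_n: int = 20
) -> tuple[frozenset, float]:
    """Exact noise-free optimum over all 2^n subsets (oracle)."""
    n = len(landscape.mutations)
    if n > max_n:
        raise ValueError(f"landscape size {n} exceeds oracle limit {max_n}")
    best_set: frozenset = frozenset()
    best_value = 0.0
    for r in range(1, n + 1):
        for combo in combinations(landscape.mutations, r):
            value = landscape.true_value(combo)
            if value > best_value:
                best_set, best_value = frozenset(combo), value
    return best_set, best_value


# -- offline experiment planning ---------------------------------------------


def parse_variant(name: str) -> frozenset:
    """Parse a '+'-joined variant name into its mutation set."""
    return frozenset(part.strip() for part in str(name).split("+") if part.strip())


def format_variant(subset) -> str:
    return "+".join(sorted(subset))


def plan_experiment(
    cluster_members: dict[int, list[str]],
    results: pd.DataFrame | None = None,
    min_improvement: float = DEFAULT_MIN_IMPROVEMENT,
) -> dict[int, dict]:
    """Propose the next round of combination variants per cluster, given the
    measurements made so far — the offline interface to wet-lab greedy
    accumulation (no evaluator is called).

    ``results`` has columns ``variant`` ('+'-joined mutation names) and
    ``delta_tm``. Measured subsets mixing mutations from different clusters
    are ignored for within-cluster planning (with a warning in the output).
    Each cluster's proposal replays the greedy rule: find the best measured
    accepted path consistent with the data, then propose its unexplored
    one-mutation extensions; a cluster with no qualifying extension left is
    marked converged.
    """
    measured: dict[frozenset, float] = {}
    warnings: list[str] = []
    if results is not None and len(results):
        for _, row in results.iterrows():
            measured[parse_variant(row["variant"])] = float(row["delta_tm"])

    member_cluster = {m: c for c, members in cluster_members.items()
                      for m in members}
    proposals: dict[int, dict] = {}
    for cluster, members in cluster_members.items():
        in_cluster: dict[frozenset, float] = {}
        for subset, value in measured.items():
            owners = {member_cluster.get(m) for m in subset}
            if owners == {cluster}:
                in_cluster[subset] = value
            elif cluster in owners and len(owners) > 1:
                warnings.append(
                    f"variant {format_variant(subset)} spans clusters "
                    f"{sorted(o for o in owners if o is not None)}; ignored"
                )
        # replay greedy acceptance against the available measurements
        current: frozenset = frozenset()
        current_value = 0.0
        remaining = [m for m in members]
        while True:
            options = [
                (m, in_cluster[current | {m}]) for m in remaining
                if current | {m} in in_cluster
            ]
            if len(options) < len(remaining):
                break  # this round is not fully measured yet
            if not options:
                break
            best_m, best_v = max(options, key=lambda mv: mv[1])
            if best_v >= current_value + min_improvement:
                current |= {best_m}
                current_value = best_v
                remaining.remove(best_m)
            else:
                remaining = []
                break
        next_round = [
            format_variant(current | {m}) for m in remaining
            if current | {m} not in in_cluster
        ]
        proposals[cluster] = {
            "current_best": format_variant(current),
            "current_delta_tm": current_value,
            "next_round": sorted(next_round),
            "converged": not next_round,
        }
    if warnings:
        proposals["warnings"] = warnings  # type: ignore[index]
    return proposals


def greedy_benchmark(
    repetitions: int,
    n: int = 8,
    effect_distribution: tuple[float, float] = (1.0, 2.0),
    epistasis_fraction: float = 0.3,
    epistasis_sd: float = 1.0,
    noise_sd: float = 0.0,
    min_improvement: float = DEFAULT_MIN_IMPROVEMENT,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo comparison of greedy accumulation against the exact
    oracle: per-repetition regret (oracle ΔTm − greedy true ΔTm of the
    greedy endpoint), evaluations used, and whether the optimum was reached."""
    if n > 20:
        raise ValueError("oracle infeasible beyond n = 20")
    rows = []
    rng = np.random.default_rng(seed)
    for rep in range(repetitions):
        land_seed = int(rng.integers(0, 2**31 - 1))
        landscape = simulate_landscape(
            n=n, effect_distribution=effect_distribution,
            epistasis_fraction=epistasis_fraction, epistasis_sd=epistasis_sd,
            noise_sd=noise_sd, seed=land_seed,
        )
        path = greedy_accumulate(
            list(landscape.mutations), landscape.measure,
            min_improvement=min_improvement,
        )
        best_set, best_value = brute_force_best(landscape)
        greedy_true = landscape.true_value(path.final_set)
        rows.append({
            "rep": rep,
            "seed": land_seed,
            "greedy_value": greedy_true,
            "oracle_value": best_value,
            "regret": best_value - greedy_true,
            "evaluations": path.evaluations_used,
            "reached_optimum": path.final_set == best_set,
        })
    return pd.DataFrame(rows)


def combine_cluster_winners(
    paths: dict[int, AccumulationPath],
    evaluate,
    min_improvement: float = DEFAULT_MIN_IMPROVEMENT,
) -> AccumulationPath:
    """Merge per-cluster winners into a final variant.

    The first proposal is the union of all per-cluster accepted sets. If the
    measured union clears ``min_improvement`` over the best single-cluster
    endpoint it is accepted; otherwise the search falls back to the best
    cluster's winner and greedily re-checks each other cluster's accepted
    mutations as individual cross-cluster additions under the same
    acceptance rule. Clusters proposing different substitutions at the same
    residue position conflict and are rejected up front.
    """
    if not paths:
        raise ValueError("need at least one cluster path")
    position_owner: dict[str, str] = {}
    collisions = []
    for path in paths.values():
        for name in path.accepted:
            pos = "".join(ch for ch in name if ch.isdigit())
            if pos in position_owner and position_owner[pos] != name:
                collisions.append((position_owner[pos], name))
            position_owner.setdefault(pos, name)
    if collisions:
        raise ValueError(f"position conflicts across clusters: {collisions}")

    best_path = max(paths.values(), key=lambda p: p.final_delta_tm)
    if len(paths) == 1:
        final = AccumulationPath(
            accepted=sorted(best_path.final_set),
            delta_tm_trace=[best_path.final_delta_tm] if best_path.accepted else [],
            stop_reason="exhausted",
        )
        return final

    union: frozenset = frozenset()
    for path in paths.values():
        union |= path.final_set
    final = AccumulationPath()
    if not union:
        final.stop_reason = "no_improvement"
        return final
    union_value = float(evaluate(union))
    final.evaluations.append((union, union_value))
    if union_value >= best_path.final_delta_tm + min_improvement or \
            union == best_path.final_set:
        final.accepted = sorted(union)
        final.delta_tm_trace = [union_value]
        final.stop_reason = "exhausted"
        return final

    # union underperforms: restart from the best cluster winner and re-check
    # each cross-cluster addition individually
    current = best_path.final_set
    current_value = best_path.final_delta_tm
    final.accepted = sorted(current)
    final.delta_tm_trace = [current_value]
    remaining = sorted(union - current)
    while remaining:
        round_results = []
        for cand in remaining:
            subset = current | {cand}
            value = float(evaluate(subset))
            final.evaluations.append((subset, value))
            round_results.append((cand, value))
        best_cand, best_value = max(round_results, key=lambda cv: cv[1])
        if best_value >= current_value + min_improvement:
            current |= {best_cand}
            current_value = best_value
            final.accepted = sorted(current)
            final.delta_tm_trace.append(best_value)
            remaining.remove(best_cand)
        else:
            break
    final.stop_reason = "no_improvement" if remaining else "exhausted"
    return final
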