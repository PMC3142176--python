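"""Neutral coalescent simulation with recombination, powering null distributions.

Ancestry is simulated with msprime (Hudson's algorithm) on a continuous
genome.  Two mutation modes are supported:

* ``theta`` — Poisson mutations at rate theta/2 per site per scaled time unit
  (infinite-sites), so that E[pi] = theta and E[S] = theta_locus * a1.
* ``fixed_s`` — exactly S mutations placed multinomially proportional to
  branch length across the marginal trees (the standard approximation for
  conditioning on the observed number of segregating sites).

Scaling: haploid samples with population size 1, so a pair of lineages
coalesces at rate 1 (E[T2] = 1).  In these units a per-site population
mutation rate theta corresponds to an msprime mutation rate theta/2, and a
per-site population recombination rate rho ( = 4*N0*r in the usual diploid
notation) to an msprime recombination rate rho/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import msprime
import numpy as np


@dataclass
class CoalescentReplicate:
    """One simulated haplotype sample."""

    matrix: np.ndarray        # (n, S_rep) 0/1 ancestral/derived
    positions: np.ndarray     # mutation positions scaled to (0, 1]
    site_coords: np.ndarray   # unique 1-based discrete coordinates in [1, L]
    num_trees: int
    replicate_index: int
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]

    @property
    def num_breakpoints(self) -> int:
        """Marginal-tree changes: an upper bound proxy for detectable events."""
        return self.num_trees - 1


@dataclass
class NullDistribution:
    statistic: str
    values: np.ndarray  # sorted, NaN-free
    n_undefined: int
    quantile_levels: tuple
    quantiles: np.ndarray
    params: dict

    def empirical_p(self, observed: float, tail: str = "two-sided") -> float:
        """Empirical p-value of an observed statistic against this null.

        Uses the (b+1)/(B+1) convention.  ``tail`` is "upper", "lower" or
        "two-sided" (twice the smaller one-tailed p, capped at 1).
        """
        vals = self.values
        B = len(vals)
        if B == 0:
            return float("nan")
        upper = (np.sum(vals >= observed) + 1) / (B + 1)
        lower = (np.sum(vals <= observed) + 1) / (B + 1)
        if tail == "upper":
            return float(upper)
        if tail == "lower":
            return float(lower)
        return float(min(1.0, 2 * min(upper, lower)))


class SimulationResourceError(RuntimeError):
    pass


def _discretize_positions(
    positions: np.ndarray, L: int, rng: np.random.Generator
) -> np.ndarray:
    """Map continuous positions on (0, L] to unique 1-based discrete sites.

    Collisions after rounding are re-drawn uniformly among free coordinates.
    """
    if len(positions) > L:
        raise SimulationResourceError(
            f"cannot place {len(positions)} mutations on {L} discrete sites"
        )
    coords = np.ceil(positions).astype(int)
    coords = np.clip(coords, 1, L)
    used = set()
    out = np.empty(len(coords), dtype=int)
    collisions = []
    for i, c in enumerate(coords):
        if c in used:
            collisions.append(i)
        else:
            used.add(c)
            out[i] = c
    if collisions:
        free = np.array(sorted(set(range(1, L + 1)) - used))
        redraw = rng.choice(len(free), size=len(collisions), replace=False)
        for i, j in zip(collisions, redraw):
            out[i] = free[j]
    order = np.argsort(out)
    return out, order


def _fixed_s_mutations(ts, S: int, rng: np.random.Generator):
    """Place exactly S mutations multinomially on branch length."""
    trees = ts.aslist()  # independent tree copies (the iterator reuses one)
    weights = np.array(
        [t.total_branch_length * t.span for t in trees], dtype=float
    )
    if weights.sum() <= 0:
        raise SimulationResourceError("degenerate genealogy (no branch length)")
    probs = weights / weights.sum()
    tree_choice = rng.choice(len(trees), size=S, p=probs)
    n = ts.num_samples
    matrix = np.zeros((n, S), dtype=np.int8)
    positions = np.empty(S, dtype=float)
    for k, ti in enumerate(tree_choice):
        tree = trees[ti]
        nodes = [
            u
            for u in tree.nodes()
            if tree.parent(u) != -1 and tree.branch_length(u) > 0
        ]
        lengths = np.array([tree.branch_length(u) for u in nodes])
        u = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
        left, right = tree.interval.left, tree.interval.right
        positions[k] = rng.uniform(left, right)
        for s in tree.samples(u):
            matrix[s, k] = 1
    order = np.argsort(positions)
    return matrix[:, order], positions[order]


def simulate_sample(
    n: int,
    L: int,
    mode: str,
    value: float,
    rho_per_site: float = 0.0,
    reps: int = 1,
    seed: int | None = None,
    max_trees: int = 100_000,
) -> Iterator[CoalescentReplicate]:
    """Stream coalescent replicates.

    Parameters
    ----------
    mode : "theta" (``value`` = theta per site) or "fixed_s" (``value`` = S).
    rho_per_site : population recombination rate 4*N0*r per site.
    max_trees : event cap guarding against runaway ARGs for huge rho*L.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if rho_per_site < 0:
        raise ValueError("rho must be >= 0")
    if mode not in ("theta", "fixed_s"):
        raise ValueError(f"unknown mode {mode!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    params = {
        "n": n, "L": L, "mode": mode, "value": value,
        "rho_per_site": rho_per_site, "reps": reps, "seed": seed,
    }
    for rep in range(reps):
        anc_seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=1.0,
            sequence_length=L,
            recombination_rate=rho_per_site / 2.0,
            discrete_genome=False,
            random_seed=anc_seed,
        )
        if ts.num_trees > max_trees:
            raise SimulationResourceError(
                f"ancestral graph produced {ts.num_trees} marginal trees "
                f"(cap {max_trees}); reduce rho*L or raise max_trees"
            )
        if mode == "theta":
            mut_seed = int(rng.integers(1, 2**31 - 1))
            mts = msprime.sim_mutations(
                ts,
                rate=value / 2.0,
                model=msprime.BinaryMutationModel(),
                discrete_genome=False,
                random_seed=mut_seed,
            )
            matrix = mts.genotype_matrix().T.astype(np.int8)
            positions = np.array(
                [site.position for site in mts.sites()], dtype=float
            )
        else:
            matrix, positions = _fixed_s_mutations(ts, int(value), rng)
        if len(positions):
            site_coords, order = _discretize_positions(positions, L, rng)
            matrix = matrix[:, order]
            site_coords = site_coords[order]
            # after collision redraws the continuous positions may disagree
            # with the discrete coordinates; report the discrete ones scaled
            positions = site_coords.astype(float)
        else:
            site_coords = np.array([], dtype=int)
        yield CoalescentReplicate(
            matrix=matrix,
            positions=positions / L,
            site_coords=site_coords,
            num_trees=ts.num_trees,
            replicate_index=rep,
            params=params,
        )


def null_distribution(
    statistic: Callable[[CoalescentReplicate], float],
    n: int,
    S: int,
    rho_per_site: float,
    L: int,
    reps: int = 10_000,
    seed: int | None = None,
    quantiles: tuple = (0.005, 0.995),
    statistic_name: str | None = None,
) -> NullDistribution:
    """Simulated null distribution of a statistic, conditional on (n, S, L, rho).

    The statistic is called with each :class:`CoalescentReplicate`; NaN
    returns count as undefined and are dropped (with a warning recorded when
    they exceed half the replicates).
    """
    values = np.empty(reps)
    for i, rep in enumerate(
        simulate_sample(n, L, "fixed_s", S, rho_per_site, reps, seed)
    ):
        values[i] = statistic(rep)
    defined = values[~np.isnan(values)]
    n_undef = reps - len(defined)
    if n_undef > reps / 2:
        import warnings

        warnings.warn(
            f"statistic undefined on {n_undef}/{reps} replicates; "
            "p-values computed over defined replicates only"
        )
    defined.sort()
    q = (
        np.quantile(defined, quantiles)
        if len(defined)
        else np.full(len(quantiles), np.nan)
    )
    return NullDistribution(
        statistic=statistic_name or getattr(statistic, "__name__", "statistic"),
        values=defined,
        n_undefined=n_undef,
        quantile_levels=tuple(quantiles),
        quantiles=q,
        params={"n": n, "S": S, "rho_per_site": rho_per_site, "L": L,
                "reps": reps, "seed": seed},
    )


def write_ms_like(replicates, path: str, command: str = "popgenkit simulate"):
    """Write replicates in ms-compatible text (segsites/positions/haplotypes)."""
    with open(path, "w") as fh:
        first = True
        for rep in replicates:
            if first:
                fh.write(f"{command}\n{rep.params.get('seed', 0)}\n")
                first = False
            fh.write("\n//\n")
            fh.write(f"segsites: {rep.S}\n")
            if rep.S:
                fh.write(
                    "positions: "
                    + " ".join(f"{p:.6f}" for p in rep.positions)
                    + "\n"
                )
                for row in rep.matrix:
                    fh.write("".join(str(int(x)) for x in row) + "\n")
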