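"""Stochastic evolution of a duplicated cis-regulatory block.

A cluster of N elements sits upstream of its target gene, with a
fraction ``q`` of element pairs functionally interacting (pairs drawn
uniformly once per replicate).  After duplication both copies start
intact.  Mutational events — single-element knockouts, or synteny
breaks that permanently disconnect every element distal to the break —
strike one copy at a time and are accepted only if afterwards every
interacting pair still has *both* members connected to the target gene
in at least one common copy (and, under the default stand-alone
constraint, every element remains connected somewhere).  The process
runs to fixation: the state where no remaining event is acceptable.

Endpoints are tallied exactly like empirical retention patterns:
``a`` elements connected only in the larger surviving copy, ``b`` in
both, ``c`` only in the smaller copy, labelled by the winner /
concordant / reciprocal rule.  At full connectivity (q = 1) fixation is
provably always winner-takes-all: two cliques can cover the complete
pair graph only if one copy keeps every element.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .retention import classify_pattern


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SimConfig:
    n_elements: int = 20
    q: float = 0.6
    n_reps: int = 10_000
    seed: int = 0
    standalone_constraint: bool = True
    # relative proposal rates: (knockout, synteny break)
    event_weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("need at least 2 elements")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def n_pairs(self) -> int:
        total = self.n_elements * (self.n_elements - 1) // 2
        return _round_half_up(self.q * total)


@dataclass
class GrbState:
    """Two cluster copies plus the (fixed) interaction graph.

    ``conn[copy, i]`` — element i still connected to the target gene in
    that copy.  Elements are indexed by genomic position, 0 = nearest
    the target gene.
    """

    conn: np.ndarray             # bool, shape (2, N)
    pairs: np.ndarray            # int, shape (P, 2)
    adjacency: np.ndarray        # bool, shape (N, N)

    @property
    def n_elements(self) -> int:
        return self.conn.shape[1]


@dataclass
class SimEndpoint:
    surviving: tuple[frozenset, frozenset]
    a: int
    b: int
    c: int
    label: str | None
    n_events: int
    major_copy: int
    major_tie: bool = False


def init_replicate(config: SimConfig, rng: np.random.Generator) -> GrbState:
    n = config.n_elements
    all_pairs = np.array(
        [(i, j) for i in range(n) for j in range(i + 1, n)], dtype=int
    )
    k = config.n_pairs
    idx = rng.choice(len(all_pairs), size=k, replace=False) if k else []
    pairs = all_pairs[list(idx)].reshape(-1, 2)
    adj = np.zeros((n, n), dtype=bool)
    for i, j in pairs:
        adj[i, j] = adj[j, i] = True
    return GrbState(conn=np.ones((2, n), dtype=bool), pairs=pairs, adjacency=adj)


def _removable(state: GrbState, copy: int, standalone: bool) -> np.ndarray:
    """Per-element test: may element i be disconnected from ``copy``
    (alone or as part of a set removed together)?

    Removing any set S from one copy is acceptable iff every element of
    S individually passes this test: each pair involving a removed
    element must be fully connected in the other copy, and (stand-alone
    rule) the element itself must survive in the other copy.
    """
    other = state.conn[1 - copy]
    not_other = ~other
    deg = state.adjacency.any(axis=1)
    pair_unsafe = deg & (not_other | (state.adjacency & not_other).any(axis=1))
    ok = state.conn[copy] & ~pair_unsafe
    if standalone:
        ok &= other
    return ok


def enumerate_events(
    state: GrbState, config: SimConfig
) -> tuple[list[tuple], np.ndarray]:
    """All acceptable events with their proposal weights.

    Events are ("ko", copy, element) or ("break", copy, gap) where gap g
    disconnects the connected elements ranked > g (g >= 1: no break
    between the target gene and the proximal element).  Weighted
    sampling over this set is equivalent to uniform-weighted proposal
    over all syntactic events with rejection of unacceptable ones.
    """
    w_ko, w_break = config.event_weights
    events: list[tuple] = []
    weights: list[float] = []
    for copy in (0, 1):
        ok = _removable(state, copy, config.standalone_constraint)
        for i in np.flatnonzero(ok):
            events.append(("ko", copy, int(i)))
            weights.append(w_ko)
        idx = np.flatnonzero(state.conn[copy])
        if len(idx) >= 2:
            rem = ok[idx]
            suffix_ok = np.logical_and.accumulate(rem[::-1])[::-1]
            for g in range(1, len(idx)):
                if suffix_ok[g]:
                    events.append(("break", copy, g))
                    weights.append(w_break)
    return events, np.asarray(weights, dtype=float)


def apply_event(state: GrbState, event: tuple) -> None:
    kind, copy, arg = event
    if kind == "ko":
        state.conn[copy, arg] = False
    else:
        idx = np.flatnonzero(state.conn[copy])
        state.conn[copy, idx[arg:]] = False


def _endpoint(state: GrbState, n_events: int) -> SimEndpoint:
    counts = state.conn.sum(axis=1)
    tie = counts[0] == counts[1]
    major = 0 if counts[0] >= counts[1] else 1
    in_major = state.conn[major]
    in_minor = state.conn[1 - major]
    a = int((in_major & ~in_minor).sum())
    b = int((in_major & in_minor).sum())
    c = int((~in_major & in_minor).sum())
    label = classify_pattern(a, b, c) if a + b + c > 0 else None
    return SimEndpoint(
        surviving=(
            frozenset(np.flatnonzero(state.conn[0]).tolist()),
            frozenset(np.flatnonzero(state.conn[1]).tolist()),
        ),
        a=a, b=b, c=c, label=label, n_events=n_events,
        major_copy=major, major_tie=bool(tie),
    )


def run_to_fixation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimEndpoint:
    """One replicate: draw the interaction graph, then apply accepted
    events until exhaustive enumeration finds none acceptable."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    state = init_replicate(config, rng)
    n_events = 0
    while True:
        events, weights = enumerate_events(state, config)
        if not events:
            return _endpoint(state, n_events)
        p = weights / weights.sum()
        event = events[int(rng.choice(len(events), p=p))]
        apply_event(state, event)
        n_events += 1


def simulate(config: SimConfig) -> list[SimEndpoint]:
    rng = np.random.default_rng(config.seed)
    return [run_to_fixation(config, rng) for _ in range(config.n_reps)]


def label_fractions(endpoints: list[SimEndpoint]) -> dict[str, float]:
    n = len(endpoints)
    counts = {"winner": 0, "concordant": 0, "reciprocal": 0, "unlabelled": 0}
    for e in endpoints:
        counts[e.label if e.label else "unlabelled"] += 1
    return {k: v / n for k, v in counts.items()}


def sweep(
    n_values: list[int],
    q_values: list[float],
    n_reps: int = 10_000,
    seed: int = 0,
    standalone_constraint: bool = True,
    event_weights: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Winner / concordant / reciprocal endpoint fractions on an (N, q)
    grid, with the binomial standard error of the winner fraction."""
    rows = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(n_values) * len(q_values))
    k = 0
    for n in n_values:
        for q in q_values:
            cfg = SimConfig(
                n_elements=n, q=q, n_reps=n_reps,
                standalone_constraint=standalone_constraint,
                event_weights=event_weights,
            )
            rng = np.random.default_rng(children[k])
            k += 1
            eps = [run_to_fixation(cfg, rng) for _ in range(n_reps)]
            frac = label_fractions(eps)
            fw = frac["winner"]
            rows.append(
                {
                    "N": n, "q": q, "reps": n_reps,
                    "frac_winner": fw,
                    "frac_concordant": frac["concordant"],
                    "frac_reciprocal": frac["reciprocal"],
                    "se": float(np.sqrt(fw * (1 - fw) / n_reps)),
                }
            )
    return pd.DataFrame(rows)


def plot_sweep(df: pd.DataFrame, path: str) -> None:
    """Winner fraction vs q, one line per N (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for n, group in df.groupby("N"):
        g = group.sort_values("q")
        ax.errorbar(g["q"], g["frac_winner"], yerr=g["se"], label=f"N={n}")
    ax.set_xlabel("connectivity q")
    ax.set_ylabel("winner-takes-all fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
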