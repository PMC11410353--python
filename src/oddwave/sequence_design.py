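"""Constrained pseudorandom oddball sequence design.

Builds the trial plans of a passive auditory oddball session: each block
opens with 16 habituation standards, then alternates runs of 4-9 standards
with single deviants (40 deviants over 271 pseudorandom standards), and ends
with one final standard -- 328 trials per block.  A session contains each of
the six deviant conditions (two per contrast: tense, voicing, VOT) three
times, 18 blocks and 5,904 trials, with no condition occurring twice in a
row.  Inter-trial intervals are uniform integers in [900, 1100] ms
(offset-to-onset).

Run lengths are sampled exactly uniformly over all bounded compositions of
the standard count, via dynamic-programming counts; tokens are chosen
i.i.d. uniformly within each role's inventory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict


import numpy as np
import pandas as pd

from ._rng import substream, randbelow

__all__ = [
    "TokenInventory",
    "Trial",
    "BlockPlan",
    "SessionPlan",
    "INVENTORIES",
    "SIBLING_CONDITION",
    "CONDITION_CONTRAST",
    "count_compositions",
    "enumerate_compositions",
    "sample_run_lengths",
    "build_block",
    "build_session",
]

# ---------------------------------------------------------------------------
# Token inventories (word list for the experiment)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TokenInventory:
    """Deviant and standard token sets for one deviant condition."""

    contrast: str                       # "tense" | "voicing" | "vot"
    deviant_condition: str              # e.g. "past", "+voi", "+asp"
    deviant_tokens: tuple[str, ...]
    critical_standard_tokens: tuple[str, ...]
    extra_standard_tokens: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.deviant_tokens) & set(self.standard_tokens):
            raise ValueError("deviant and standard token sets must be disjoint")

    @property
    def standard_tokens(self) -> tuple[str, ...]:
        return self.critical_standard_tokens + self.extra_standard_tokens


_PAST = ("gave", "met", "sank")
_PRESENT = ("pave", "get", "thank")
_EXTRA_PAST = ("chose", "sang", "bled", "swore", "clung", "pled", "grew", "drew", "brought")
_EXTRA_PRESENT = ("choose", "sing", "bleed", "swear", "cling", "plead", "grow", "woo", "bring")
_VOICED = ("ba", "da", "ga", "va", "za")
_VOICELESS = ("pa", "ta", "ka", "fa", "sa")

#: The six deviant conditions of the experiment, keyed by condition label.
INVENTORIES: dict[str, TokenInventory] = {
    "present": TokenInventory("tense", "present", _PRESENT, _PAST, _EXTRA_PAST),
    "past": TokenInventory("tense", "past", _PAST, _PRESENT, _EXTRA_PRESENT),
    "+voi": TokenInventory("voicing", "+voi", _VOICED, _VOICELESS),
    "-voi": TokenInventory("voicing", "-voi", _VOICELESS, _VOICED),
    "+asp": TokenInventory("vot", "+asp", ("pa",), ("ba",)),
    "-asp": TokenInventory("vot", "-asp", ("ba",), ("pa",)),
}

#: The other condition of the same contrast: the block type in which one
#: condition's deviant tokens serve as (critical) standards.
SIBLING_CONDITION: dict[str, str] = {
    "present": "past", "past": "present",
    "+voi": "-voi", "-voi": "+voi",
    "+asp": "-asp", "-asp": "+asp",
}

CONDITION_CONTRAST: dict[str, str] = {c: inv.contrast for c, inv in INVENTORIES.items()}


# ---------------------------------------------------------------------------
# Trials and plans
# ---------------------------------------------------------------------------


@dataclass
class Trial:
    index_in_block: int
    role: str                 # "standard" | "deviant"
    segment: str              # "habituation" | "pseudorandom" | "final"
    token: str
    iti_ms: int
    analyzable: bool = True   # set by oddwave.immn.mark_analyzable


@dataclass
class BlockPlan:
    block_type: str
    trials: list[Trial]
    rng_seed_path: tuple = ()

    @property
    def n_deviants(self) -> int:
        return sum(t.role == "deviant" for t in self.trials)

    def run_lengths_before_deviants(self) -> list[int]:
        """Length of the unbroken standard run preceding each deviant.

        Habituation trials do not count toward the first run.
        """
        runs, current = [], 0
        for t in self.trials:
            if t.segment == "habituation":
                continue
            if t.role == "deviant":
                runs.append(current)
                current = 0
            else:
                current += 1
        return runs


@dataclass
class SessionPlan:
    participant_id: str
    master_seed: int
    blocks: list[BlockPlan] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)

    def block_types(self) -> list[str]:
        return [b.block_type for b in self.blocks]

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None, indent: int = 1):
        payload = {
            "participant_id": self.participant_id,
            "master_seed": self.master_seed,
            "blocks": [
                {
                    "block_type": b.block_type,
                    "rng_seed_path": list(b.rng_seed_path),
                    "trials": [asdict(t) for t in b.trials],
                }
                for b in self.blocks
            ],
        }
        text = json.dumps(payload, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SessionPlan":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        blocks = [
            BlockPlan(
                block_type=b["block_type"],
                rng_seed_path=tuple(b["rng_seed_path"]),
                trials=[Trial(**t) for t in b["trials"]],
            )
            for b in payload["blocks"]
        ]
        return cls(payload["participant_id"], payload["master_seed"], blocks)

    def to_frame(self) -> pd.DataFrame:
        """Flat trial log: one row per trial."""
        rows = []
        for bi, b in enumerate(self.blocks):
            for t in b.trials:
                rows.append(
                    (bi, t.index_in_block, b.block_type, t.segment, t.role,
                     t.token, t.iti_ms, t.analyzable)
                )
        return pd.DataFrame(
            rows,
            columns=["block", "trial", "block_type", "segment", "role",
                     "token", "iti_ms", "analyzable"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Uniform sampling of bounded compositions
# ---------------------------------------------------------------------------


_COMP_TABLES: dict[tuple[int, int], list[list[int]]] = {}


def _composition_table(min_len: int, max_len: int, n_runs: int) -> list[list[int]]:
    """Bottom-up DP table: table[r][t] = #compositions of t into r bounded parts."""
    tab = _COMP_TABLES.setdefault((min_len, max_len), [[1]])
    while len(tab) <= n_runs:
        r = len(tab)
        prev = tab[r - 1]
        row = [0] * (r * max_len + 1)
        for t in range(r * min_len, r * max_len + 1):
            acc = 0
            for k in range(min_len, max_len + 1):
                pt = t - k
                if 0 <= pt < len(prev):
                    acc += prev[pt]
            row[t] = acc
        tab.append(row)
    return tab


def count_compositions(n_runs: int, total: int, min_len: int, max_len: int) -> int:
    """Number of ordered tuples of ``n_runs`` integers in [min_len, max_len]
    summing to ``total`` (exact, arbitrary precision)."""
    if n_runs < 0 or total < 0:
        return 0
    tab = _composition_table(min_len, max_len, n_runs)
    row = tab[n_runs]
    return row[total] if total < len(row) else 0


def enumerate_compositions(n_runs: int, total: int, min_len: int, max_len: int):
    """Yield every bounded composition (small instances; test oracle)."""
    if n_runs == 0:
        if total == 0:
            yield ()
        return
    for k in range(min_len, max_len + 1):
        for rest in enumerate_compositions(n_runs - 1, total - k, min_len, max_len):
            yield (k,) + rest


def sample_run_lengths(
    n_runs: int, total: int, min_len: int, max_len: int, rng: np.random.Generator
) -> list[int]:
    """Draw run lengths uniformly over all bounded compositions.

    Sequential conditional sampling: the first length is chosen with
    probability proportional to the exact count of completions, which makes
    the joint draw exactly uniform over the composition set.
    """
    if n_runs < 1 or min_len < 1 or max_len < min_len:
        raise ValueError("need n_runs >= 1 and 1 <= min_len <= max_len")
    lo, hi = n_runs * min_len, n_runs * max_len
    if not lo <= total <= hi:
        raise ValueError(
            f"no composition of {total} into {n_runs} parts in "
            f"[{min_len}, {max_len}]; feasible totals are [{lo}, {hi}]"
        )
    out: list[int] = []
    remaining = total
    for runs_left in range(n_runs, 0, -1):
        total_count = count_compositions(runs_left, remaining, min_len, max_len)
        u = randbelow(total_count, rng)
        for k in range(min_len, max_len + 1):
            c = count_compositions(runs_left - 1, remaining - k, min_len, max_len)
            if u < c:
                out.append(k)
                remaining -= k
                break
            u -= c
        else:  # pragma: no cover - unreachable if counts are consistent
            raise AssertionError("composition sampling walked off the count table")
    return out


# ---------------------------------------------------------------------------
# Blocks and sessions
# ---------------------------------------------------------------------------

ITI_RANGE_MS = (900, 1100)
N_HABITUATION = 16
N_DEVIANTS = 40
N_RUN_STANDARDS = 271
RUN_MIN, RUN_MAX = 4, 9


def _draw_iti(rng: np.random.Generator) -> int:
    return int(rng.integers(ITI_RANGE_MS[0], ITI_RANGE_MS[1] + 1))


def build_block(
    block_type: str,
    inventory: TokenInventory | None = None,
    rng: np.random.Generator | None = None,
    *,
    n_habituation: int = N_HABITUATION,
    n_deviants: int = N_DEVIANTS,
    n_run_standards: int = N_RUN_STANDARDS,
    run_min: int = RUN_MIN,
    run_max: int = RUN_MAX,
    rng_seed_path: tuple = (),
) -> BlockPlan:
    """Build one oddball block for ``block_type``.

    The keyword arguments default to the experiment's design numbers
    (16 + 271 + 40 + 1 = 328 trials) and may be reduced for scaled-down
    simulation studies.
    """
    if inventory is None:
        if block_type not in INVENTORIES:
            raise KeyError(f"unknown block type {block_type!r}; known: {sorted(INVENTORIES)}")
        inventory = INVENTORIES[block_type]
    if inventory.deviant_condition != block_type:
        raise ValueError(
            f"inventory is for condition {inventory.deviant_condition!r}, "
            f"not block type {block_type!r}"
        )
    if rng is None:
        rng = np.random.default_rng()

    std = inventory.standard_tokens
    dev = inventory.deviant_tokens
    runs = sample_run_lengths(n_deviants, n_run_standards, run_min, run_max, rng)

    trials: list[Trial] = []

    def add(role: str, segment: str, tokens) -> None:
        token = tokens[int(rng.integers(len(tokens)))]
        trials.append(Trial(len(trials), role, segment, token, _draw_iti(rng)))

    for _ in range(n_habituation):
        add("standard", "habituation", std)
    for run in runs:
        for _ in range(run):
            add("standard", "pseudorandom", std)
        add("deviant", "pseudorandom", dev)
    add("standard", "final", std)

    return BlockPlan(block_type=block_type, trials=trials, rng_seed_path=rng_seed_path)


def _draw_block_order(
    conditions: list[str], n_reps: int, rng: np.random.Generator
) -> tuple[list[str], int]:
    """Uniform draw over orderings with no adjacent repeats, by rejection."""
    types = list(conditions) * n_reps
    attempts = 0
    while True:
        attempts += 1
        order = [types[i] for i in rng.permutation(len(types))]
        if all(a != b for a, b in zip(order, order[1:])):
            return order, attempts


def build_session(
    master_seed: int,
    participant_id: str = "sim",
    *,
    conditions: list[str] | None = None,
    n_reps: int = 3,
    inventories: dict[str, TokenInventory] | None = None,
    **block_kwargs,
) -> SessionPlan:
    """Build a full session: each condition ``n_reps`` times, no adjacent
    repeats, all randomness drawn from named substreams of ``master_seed``."""
    conditions = list(INVENTORIES) if conditions is None else list(conditions)
    inventories = INVENTORIES if inventories is None else inventories
    order, _ = _draw_block_order(conditions, n_reps, substream(master_seed, "block-order"))
    blocks = []
    for i, block_type in enumerate(order):
        path = ("block", i)
        blocks.append(
            build_block(
                block_type,
                inventories[block_type],
                substream(master_seed, *path),
                rng_seed_path=path,
                **block_kwargs,
            )
        )
    return SessionPlan(participant_id=participant_id, master_seed=master_seed, blocks=blocks)
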