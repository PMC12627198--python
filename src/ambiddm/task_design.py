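"""Trial grids and session assembly for the two-domain ambiguity choice task.

Every trial offers a constant hidden option (5 euro, now, for sure) against a
variable option shown on screen.  In the delay domain the variable option is a
later-larger reward with an exact delay or an ambiguous delay range; in the
probability domain it is a risky reward with an exact or ambiguous win
probability.  A session interleaves seven delay blocks and seven probability
blocks (15 trials each: 14 choice trials plus one catch trial), 210 trials in
total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

# Design constants of the constant (sooner-smaller / sure) option.
V_CONSTANT = 5.0   # euros, both domains
D_CONSTANT = 0.0   # days (immediate)
P_CONSTANT = 1.0   # certain

AMOUNTS = (8.0, 15.0, 22.0, 29.0, 36.0, 43.0, 50.0)

# Nine exact delay levels (days).  The printed list in the source task has
# eight values for a claimed nine levels; 124 restores the ladder symmetric
# around 100 days and coincides with the 76-124 ambiguous range endpoints.
EXACT_DELAYS = (10.0, 26.0, 50.0, 76.0, 100.0, 124.0, 150.0, 174.0, 190.0)
AMB_DELAY_WIDTHS = (0.0, 48.0, 100.0, 148.0, 200.0)   # midpoint always 100 d
AMB_DELAY_MIDPOINT = 100.0

EXACT_PROBS = (0.05, 0.13, 0.25, 0.38, 0.50, 0.62, 0.75, 0.87, 0.95)
AMB_PROB_WIDTHS = (0.0, 0.24, 0.50, 0.74, 1.00)       # midpoint always 0.5
AMB_PROB_MIDPOINT = 0.5

N_BLOCKS = 14
TRIALS_PER_BLOCK = 15
CHOICE_TRIALS_PER_BLOCK = TRIALS_PER_BLOCK - 1
SESSION_LENGTH = N_BLOCKS * TRIALS_PER_BLOCK  # 210

TRIAL_COLUMNS = [
    "block", "trial_index", "domain", "kind", "amount",
    "delay_days", "prob_win", "amb_days", "amb_prob",
]


@dataclass(frozen=True)
class Trial:
    """One design cell: attributes of the variable option.

    ``delay_days`` and ``prob_win`` hold the midpoint for ambiguous trials;
    ``amb_days`` / ``amb_prob`` hold the full range width (0 when exact).
    """

    domain: str                 # "delay" | "probability"
    kind: str                   # "exact" | "ambiguous" | "catch"
    amount: float               # euros
    delay_days: float = 0.0
    prob_win: float = 1.0
    amb_days: float = 0.0
    amb_prob: float = 0.0
    block: int = 0

    def __post_init__(self) -> None:
        if self.domain not in ("delay", "probability"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.kind not in ("exact", "ambiguous", "catch"):
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if self.kind == "ambiguous":
            if self.domain == "delay" and self.delay_days != AMB_DELAY_MIDPOINT:
                raise ValueError("ambiguous delay trials sit at the 100-day midpoint")
            if self.domain == "probability" and self.prob_win != AMB_PROB_MIDPOINT:
                raise ValueError("ambiguous probability trials sit at the 50% midpoint")
        if self.kind == "catch" and self.amount != V_CONSTANT:
            raise ValueError("catch trials offer the constant amount (5 euro)")


@dataclass
class Session:
    """An ordered 210-trial session for one participant."""

    trials: list[Trial]
    seed: int
    first_domain: str = "delay"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trials):
            d = asdict(t)
            d["trial_index"] = i
            rows.append(d)
        return pd.DataFrame(rows)[TRIAL_COLUMNS]


def build_intertemporal_grid() -> list[Trial]:
    """The 98 unique intertemporal trials: 7 amounts x 9 exact delays plus
    7 amounts x 5 ambiguity widths (amount-major, attribute ascending)."""
    grid: list[Trial] = []
    for a in AMOUNTS:
        for d in EXACT_DELAYS:
            grid.append(Trial("delay", "exact", a, delay_days=d))
    for a in AMOUNTS:
        for w in AMB_DELAY_WIDTHS:
            grid.append(Trial("delay", "ambiguous", a,
                              delay_days=AMB_DELAY_MIDPOINT, amb_days=w))
    return grid


def build_risky_grid() -> list[Trial]:
    """The 98 unique risky trials: 7 amounts x 9 exact probabilities plus
    7 amounts x 5 ambiguity widths."""
    grid: list[Trial] = []
    for a in AMOUNTS:
        for p in EXACT_PROBS:
            grid.append(Trial("probability", "exact", a, prob_win=p))
    for a in AMOUNTS:
        for w in AMB_PROB_WIDTHS:
            grid.append(Trial("probability", "ambiguous", a,
                              prob_win=AMB_PROB_MIDPOINT, amb_prob=w))
    return grid


def _catch_trial(domain: str) -> Trial:
    # Attention check: variable amount equals the constant 5 euro; mid-level
    # exact attribute so the trial is otherwise unremarkable.
    if domain == "delay":
        return Trial("delay", "catch", V_CONSTANT, delay_days=100.0)
    return Trial("probability", "catch", V_CONSTANT, prob_win=0.5)


def assemble_session(seed: int) -> Session:
    """Shuffle both grids into 14 alternating 15-trial blocks, one catch trial
    per block; fully reproducible given ``seed``."""
    itc = build_intertemporal_grid()
    risky = build_risky_grid()
    n_blocks_per_domain = N_BLOCKS // 2
    for name, grid in (("intertemporal", itc), ("risky", risky)):
        if len(grid) != n_blocks_per_domain * CHOICE_TRIALS_PER_BLOCK:
            raise ValueError(
                f"{name} grid has {len(grid)} trials; cannot form "
                f"{n_blocks_per_domain} blocks of {CHOICE_TRIALS_PER_BLOCK}")

    rng = np.random.default_rng(seed)
    order_itc = rng.permutation(len(itc))
    order_risky = rng.permutation(len(risky))
    first_domain = "delay" if seed % 2 == 0 else "probability"

    streams = {
        "delay": [itc[i] for i in order_itc],
        "probability": [risky[i] for i in order_risky],
    }
    trials: list[Trial] = []
    for b in range(N_BLOCKS):
        domain = first_domain if b % 2 == 0 else (
            "probability" if first_domain == "delay" else "delay")
        stream = streams[domain]
        block_trials = stream[:CHOICE_TRIALS_PER_BLOCK]
        del stream[:CHOICE_TRIALS_PER_BLOCK]
        pos = int(rng.integers(0, TRIALS_PER_BLOCK))
        block_trials.insert(pos, _catch_trial(domain))
        for t in block_trials:
            trials.append(Trial(t.domain, t.kind, t.amount, t.delay_days,
                                t.prob_win, t.amb_days, t.amb_prob, block=b + 1))
    return Session(trials=trials, seed=seed, first_domain=first_domain)


def session_to_csv(session: Session, path) -> None:
    session.to_frame().to_csv(path, index=False)


def trials_from_frame(df: pd.DataFrame) -> list[Trial]:
    """Rebuild Trial objects from the tabular form (inverse of to_frame)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(Trial(row.domain, row.kind, float(row.amount),
                         float(row.delay_days), float(row.prob_win),
                         float(row.amb_days), float(row.amb_prob),
                         block=int(row.block)))
    return out
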