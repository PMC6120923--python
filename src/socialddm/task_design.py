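"""Mini-dictator-game payoff design.

Each game is a binary allocation problem between a *selfish* option (more
money for the dictator) and a *pro-social* option (more money for the
receiver, less inequality).  The design crosses the dictator payoff
difference ``DicDiff`` in {2, 4, 6, 8, 10} with the receiver payoff
difference ``ReceDiff`` in {3, 9, ..., 57} (steps of 6), giving 50 cells.
Both options always leave the dictator with the larger payoff, so only
advantageous inequality is in play.

Games 1-50 are the first time-free block.  The time-pressure and
time-delay blocks shift all four payoffs of each base game by +/-1 (one
random half down, the other up); the second time-free block (games
51-100) uses +/-2 shifts.  Shifting all payoffs by a constant leaves
``DicDiff``, ``ReceDiff`` and hence every downstream quantity (utility
differences, drift rates, indifference points) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DIC_DIFFS: tuple[int, ...] = (2, 4, 6, 8, 10)
RECE_DIFFS: tuple[int, ...] = tuple(range(3, 58, 6))
CONDITIONS: tuple[str, ...] = ("free1", "pressure", "delay", "free2")

GAME_COLUMNS = [
    "game_id",
    "condition",
    "self_selfish",
    "other_selfish",
    "self_prosocial",
    "other_prosocial",
    "dic_diff",
    "rece_diff",
]


@dataclass(frozen=True)
class Game:
    """One mini-dictator game (payoffs in points)."""

    game_id: int
    self_selfish: int
    other_selfish: int
    self_prosocial: int
    other_prosocial: int
    condition: str = "free1"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if min(self.self_selfish, self.other_selfish,
               self.self_prosocial, self.other_prosocial) <= 0:
            raise ValueError("payoffs must be positive")
        if self.dic_diff <= 0:
            raise ValueError("selfish option must pay the dictator strictly more")
        if self.rece_diff <= 0:
            raise ValueError("pro-social option must pay the receiver strictly more")
        if not (self.self_selfish > self.other_selfish
                and self.self_prosocial > self.other_prosocial):
            raise ValueError("dictator payoff must exceed receiver payoff in both options")

    @property
    def dic_diff(self) -> int:
        return self.self_selfish - self.self_prosocial

    @property
    def rece_diff(self) -> int:
        return self.other_prosocial - self.other_selfish


def generate_base_games(seed: int) -> list[Game]:
    """Generate the 50 time-free base games (one per factorial cell).

    The published design fixes only the payoff *differences*; absolute
    levels are drawn here once per cell: the selfish-option dictator
    payoff uniformly from [70, 100] and the selfish-option receiver
    payoff from [10, 25], resampled until the dictator payoff exceeds the
    receiver payoff in both options.  Levels cancel out of everything
    downstream.
    """
    rng = np.random.default_rng(seed)
    games: list[Game] = []
    gid = 1
    for dd in DIC_DIFFS:
        for rd in RECE_DIFFS:
            while True:
                self_selfish = int(rng.integers(70, 101))
                other_selfish = int(rng.integers(10, 26))
                self_prosocial = self_selfish - dd
                other_prosocial = other_selfish + rd
                if self_prosocial > other_prosocial and self_selfish > other_selfish:
                    break
            games.append(Game(gid, self_selfish, other_selfish,
                              self_prosocial, other_prosocial, "free1"))
            gid += 1
    return games


def shift_games_for_condition(base: Sequence[Game], condition: str,
                              seed: int) -> list[Game]:
    """Derive the game set of another block by shifting all payoffs.

    ``pressure`` and ``delay`` shift by -1 for a seeded random half of
    the 50 games and +1 for the other half; ``free2`` (games 51-100)
    uses +/-2.  Differences are untouched.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "free1":
        return list(base)
    magnitude = 2 if condition == "free2" else 1
    rng = np.random.default_rng(seed)
    n = len(base)
    down = np.zeros(n, dtype=bool)
    down[rng.permutation(n)[: n // 2]] = True
    id_offset = len(base) if condition == "free2" else 0
    out = []
    for i, g in enumerate(base):
        s = -magnitude if down[i] else magnitude
        out.append(Game(g.game_id + id_offset,
                        g.self_selfish + s, g.other_selfish + s,
                        g.self_prosocial + s, g.other_prosocial + s,
                        condition))
    return out


def full_design(seed: int) -> pd.DataFrame:
    """All four blocks as one games table (200 rows)."""
    base = generate_base_games(seed)
    frames = [base]
    for cond in ("pressure", "delay", "free2"):
        # distinct sub-seed per condition so the +/- halves differ between blocks
        frames.append(shift_games_for_condition(base, cond,
                                                seed * 4 + CONDITIONS.index(cond)))
    return games_to_frame([g for block in frames for g in block])


def indifference_beta(game) -> float:
    """The advantageous-inequality-aversion beta at which the two options
    have equal Fehr-Schmidt utility; equals DicDiff/(DicDiff+ReceDiff)."""
    dd, rd = _diffs(game)
    return dd / (dd + rd)


def median_indifference_beta(games) -> float:
    """Median per-game indifference beta; the selfish/pro-social cutoff."""
    if isinstance(games, pd.DataFrame):
        if games.empty:
            raise ValueError("empty games table")
        vals = games["dic_diff"] / (games["dic_diff"] + games["rece_diff"])
        return float(np.median(vals))
    games = list(games)
    if not games:
        raise ValueError("empty games list")
    return float(np.median([indifference_beta(g) for g in games]))


def _diffs(game) -> tuple[float, float]:
    if isinstance(game, Game):
        return float(game.dic_diff), float(game.rece_diff)
    # mapping-like (a DataFrame row or dict)
    return float(game["dic_diff"]), float(game["rece_diff"])


def games_to_frame(games: Iterable[Game]) -> pd.DataFrame:
    rows = [
        {
            "game_id": g.game_id,
            "condition": g.condition,
            "self_selfish": g.self_selfish,
            "other_selfish": g.other_selfish,
            "self_prosocial": g.self_prosocial,
            "other_prosocial": g.other_prosocial,
            "dic_diff": g.dic_diff,
            "rece_diff": g.rece_diff,
        }
        for g in games
    ]
    return pd.DataFrame(rows, columns=GAME_COLUMNS)


def frame_to_games(frame: pd.DataFrame) -> list[Game]:
    return [
        Game(int(r.game_id), int(r.self_selfish), int(r.other_selfish),
             int(r.self_prosocial), int(r.other_prosocial), str(r.condition))
        for r in frame.itertuples()
    ]


def write_games_csv(games, path) -> None:
    frame = games if isinstance(games, pd.DataFrame) else games_to_frame(games)
    frame.to_csv(path, index=False)


def read_games_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
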