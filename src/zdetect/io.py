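"""History CSV input/output, run configuration and fixture generation.

The on-disk history format is a plain CSV with header ``turn,player,opponent``
and one row per turn, moves strictly ``C`` or ``D``::

    turn,player,opponent
    1,C,C
    2,C,D
    ...

The reader validates strictly and reports line numbers on failure; writing
then reading a history is the identity.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np

from .measurement import PlayHistory

__all__ = [
    "read_history",
    "write_history",
    "table1_history",
    "random_memory_one_vectors",
    "RunConfig",
]

#: The worked 20-turn example match: an extortionate strategy with
#: chi = 2 (p = (8/9, 1/2, 1/3, 0)) against Alternator.  Its per-state
#: measured tallies are (2/2, 1/5, 3/8, 0/4).
_EXAMPLE_X = "CCDDDCDDDDDCCCDDDCDD"
_EXAMPLE_Y = "CDCDCDCDCDCDCDCDCDCD"


def table1_history() -> PlayHistory:
    """The bundled 20-turn extortioner-vs-Alternator example history."""
    return PlayHistory.from_strings(_EXAMPLE_X, _EXAMPLE_Y)


def write_history(history: PlayHistory, path: str | Path) -> None:
    """Write a history to CSV in the package dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["turn", "player", "opponent"])
        for t, (mx, my) in enumerate(zip(history.moves_x, history.moves_y), start=1):
            writer.writerow([t, mx, my])


def read_history(path: str | Path) -> PlayHistory:
    """Read and strictly validate a history CSV.

    Raises ``ValueError`` naming the offending line for bad symbols,
    ragged rows, out-of-order turn numbers or a missing header, and for
    histories too short to contain a transition.
    """
    moves_x: list[str] = []
    moves_y: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, no transitions") from None
        if [h.strip().lower() for h in header] != ["turn", "player", "opponent"]:
            raise ValueError(
                f"{path}: line 1: expected header 'turn,player,opponent', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
            turn_s, mx, my = (field.strip() for field in row)
            try:
                turn = int(turn_s)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: bad turn number {turn_s!r}") from None
            if turn != len(moves_x) + 1:
                raise ValueError(
                    f"{path}: line {lineno}: turn {turn} out of order (expected {len(moves_x) + 1})"
                )
            for mv in (mx, my):
                if mv not in ("C", "D"):
                    raise ValueError(
                        f"{path}: line {lineno}: moves must be 'C' or 'D', got {mv!r}"
                    )
            moves_x.append(mx)
            moves_y.append(my)
    if len(moves_x) < 2:
        raise ValueError(f"{path}: no transitions (need at least 2 turns)")
    return PlayHistory(tuple(moves_x), tuple(moves_y))


def random_memory_one_vectors(k: int, seed: int) -> np.ndarray:
    """k memory-one vectors drawn uniformly from [0, 1]^4 (seeded)."""
    rng = np.random.default_rng(seed)
    return rng.random((k, 4))


@dataclasses.dataclass
class RunConfig:
    """Provenance record attached to every CLI output."""

    command: str
    payoffs: tuple[float, float, float, float] = (3.0, 0.0, 5.0, 1.0)
    turns: int | None = None
    reps: int | None = None
    seed: int | None = None
    noise: float = 0.0
    imputation: str = "overall_rate"
    sse_threshold: float = 0.05
    corpus: str = "default"
    extra: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def write_sidecar(self, out_path: str | Path) -> Path:
        """Write the config next to an output file as ``<out>.config.json``."""
        side = Path(str(out_path) + ".config.json")
        side.write_text(self.to_json() + "\n")
        return side
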