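"""Build the 330-trial modified Simon-task sequence.

The stimulus stream is a full generation of the Fibonacci grammar
(generation 12, 233 symbols, split contiguously into blocks of 89, 89 and
55 trials) followed by generation 4 of the Skip grammar (97 symbols, block
4), presented without interruption.  Symbols map to colours (0 → red,
1 → blue), colours to response keys (red → key 1 on the left, blue → key 0
on the right), and every sixth trial is incongruent: the square appears on
the side opposite its response key.

Analysis-context flags mark the trials the three analyses compare:
``a1`` — a blue following a red (First Law), ``a2`` — a red following two
blues (Second Law), ``a3`` — a blue following a red–blue pair (a k-point in
Fib, a structurally unremarkable 1 in Skip).  Context windows read the
presentation order across block boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import pandas as pd

from .grammar import FIB, SKIP, derive
from .annotate import PointClass, classify_points, validate_three_laws

__all__ = [
    "ExperimentConfig",
    "TrialRecord",
    "ConfigError",
    "TrialParseError",
    "build_trials",
    "label_contexts",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
    "TRIAL_COLUMNS",
]

KEY_SIDE = {"key1": "left", "key0": "right"}
OPPOSITE = {"left": "right", "right": "left"}

TRIAL_COLUMNS = [
    "index", "block", "grammar", "symbol", "colour", "correct_key",
    "side", "congruency", "is_k", "a1_target", "a2_target", "a3_target",
]


class ConfigError(ValueError):
    pass


class TrialParseError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    """Design parameters of the task; defaults reproduce the experiment."""

    fib_generation: int = 12
    skip_generation: int = 4
    block_sizes: tuple[int, int, int, int] = (89, 89, 55, 97)
    incongruent_period: int = 6
    response_deadline: float = 1000.0
    colour_map: dict = field(default_factory=lambda: {"0": "red", "1": "blue"})
    seed: int = 0  # reserved; trial construction is fully deterministic

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        if self.incongruent_period < 2:
            raise ConfigError("incongruent_period must be >= 2")
        if self.response_deadline <= 0:
            raise ConfigError("response_deadline must be positive")


@dataclass(frozen=True)
class TrialRecord:
    """One Simon-task trial."""

    index: int           # 1-based position in the 330-trial stream
    block: int           # 1..4
    grammar: str         # "fib" | "skip"
    symbol: str          # "0" | "1"
    colour: str          # "red" | "blue"
    correct_key: str     # "key1" | "key0"
    side: str            # "left" | "right"
    congruency: str      # "congruent" | "incongruent"
    is_k: bool
    a1_target: bool = False
    a2_target: bool = False
    a3_target: bool = False


def build_trials(config: ExperimentConfig | None = None) -> list[TrialRecord]:
    """Assemble the full trial sequence for a configuration.

    Raises :class:`ConfigError` when the block sizes do not tile the two
    generation strings exactly.
    """
    config = config or ExperimentConfig()
    fib = derive(FIB, "0", config.fib_generation)
    skip = derive(SKIP, "0", config.skip_generation)
    fib_str = fib.generation(config.fib_generation)
    skip_str = skip.generation(config.skip_generation)

    sizes = config.block_sizes
    if sum(sizes[:3]) != len(fib_str):
        raise ConfigError(
            f"first three block sizes sum to {sum(sizes[:3])} but Fib "
            f"generation {config.fib_generation} has {len(fib_str)} symbols"
        )
    if sizes[3] != len(skip_str):
        raise ConfigError(
            f"fourth block size is {sizes[3]} but Skip generation "
            f"{config.skip_generation} has {len(skip_str)} symbols"
        )

    k_set = {
        a.pos
        for a in classify_points(fib, config.fib_generation)
        if a.point_class is PointClass.K
    }

    block_of: list[int] = []
    for b, size in enumerate(sizes, start=1):
        block_of.extend([b] * size)

    trials: list[TrialRecord] = []
    for i, sym in enumerate(fib_str + skip_str, start=1):
        in_fib = i <= len(fib_str)
        colour = config.colour_map[sym]
        key = "key1" if colour == "red" else "key0"
        congruent = i % config.incongruent_period != 0
        side = KEY_SIDE[key] if congruent else OPPOSITE[KEY_SIDE[key]]
        trials.append(
            TrialRecord(
                index=i,
                block=block_of[i - 1],
                grammar="fib" if in_fib else "skip",
                symbol=sym,
                colour=colour,
                correct_key=key,
                side=side,
                congruency="congruent" if congruent else "incongruent",
                is_k=in_fib and (i in k_set),
            )
        )
    return label_contexts(trials)


def label_contexts(trials: list[TrialRecord]) -> list[TrialRecord]:
    """Fill the a1/a2/a3 analysis flags from the presentation-order colours."""
    colours = [t.colour for t in trials]
    out: list[TrialRecord] = []
    for i, t in enumerate(trials):
        a1 = t.colour == "blue" and i >= 1 and colours[i - 1] == "red"
        a2 = (
            t.colour == "red"
            and i >= 2
            and colours[i - 2] == "blue"
            and colours[i - 1] == "blue"
        )
        a3 = (
            t.colour == "blue"
            and i >= 2
            and colours[i - 2] == "red"
            and colours[i - 1] == "blue"
        )
        out.append(replace(t, a1_target=a1, a2_target=a2, a3_target=a3))
    return out


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in trials], columns=TRIAL_COLUMNS)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialParseError(f"missing trial columns: {missing}")
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        try:
            records.append(
                TrialRecord(
                    index=int(d["index"]),
                    block=int(d["block"]),
                    grammar=str(d["grammar"]),
                    symbol=str(d["symbol"]),
                    colour=str(d["colour"]),
                    correct_key=str(d["correct_key"]),
                    side=str(d["side"]),
                    congruency=str(d["congruency"]),
                    is_k=_as_bool(d["is_k"]),
                    a1_target=_as_bool(d["a1_target"]),
                    a2_target=_as_bool(d["a2_target"]),
                    a3_target=_as_bool(d["a3_target"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise TrialParseError(
                f"malformed trial row {len(records) + 1}: {exc}"
            ) from exc
    return records


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def write_trials(trials: list[TrialRecord], path) -> None:
    """Write trials as a UTF-8 CSV with a fixed header."""
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials(path, logger=None) -> list[TrialRecord]:
    """Read a trial CSV back; warns when the symbol column breaks the laws."""
    try:
        frame = pd.read_csv(path, dtype={"symbol": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrialParseError(f"cannot parse {path}: {exc}") from exc
    trials = frame_to_trials(frame)
    report = validate_three_laws("".join(t.symbol for t in trials))
    if not report.grammatical and logger is not None:
        logger.warning(
            "trial file %s violates the Three Laws: 00 at %s, 111 at %s",
            path, report.first_law_violations, report.second_law_violations,
        )
    return trials
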