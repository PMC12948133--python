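"""Behavioral trial data model, delimited-text IO and the exclusion pipeline.

One :class:`TrialRecord` is a single stimulus presentation during the
lexical decision task: which participant, in which sleep stage, which
stimulus class (word vs pseudoword), what they answered via facial-muscle
contractions, how fast, and the artifact flags used for trial exclusion.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class Group(enum.Enum):
    HP = "HP"   # healthy participants
    NP = "NP"   # participants with narcolepsy


class Stage(enum.Enum):
    WAKE = "wake"
    N1 = "n1"
    N2 = "n2"
    N3 = "n3"
    REM = "rem"
    LUCID_REM = "lucid_rem"


class Stimulus(enum.Enum):
    WORD = "word"
    PSEUDOWORD = "pseudoword"


class Response(enum.Enum):
    WORD = "word"
    PSEUDOWORD = "pseudoword"
    NONE = "none"


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    group: Group
    session: int
    stage: Stage
    stimulus: Stimulus
    response: Response
    rt: float | None          # seconds; None iff response is NONE
    microarousal: bool = False
    n_contractions: int = 0

    def __post_init__(self):
        if self.response is Response.NONE:
            if self.rt is not None:
                raise ValueError("rt must be absent when response is NONE")
        else:
            if self.rt is None or not (self.rt >= 0):
                raise ValueError("rt must be a non-negative number for response trials")
            if self.n_contractions < 1:
                raise ValueError("response trials require at least one contraction")
        if self.n_contractions < 0:
            raise ValueError("n_contractions must be non-negative")

    @property
    def correct(self) -> bool:
        """Response matches the stimulus class; defined only for response trials."""
        if self.response is Response.NONE:
            raise ValueError("correctness undefined for non-response trials")
        return self.response.value == self.stimulus.value


COLUMNS = (
    "subject_id", "group", "session", "stage", "stimulus",
    "response", "rt", "microarousal", "n_contractions",
)


class SchemaError(ValueError):
    pass


class RowError(ValueError):
    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


def _parse_enum(cls, value, row):
    try:
        return cls(str(value).strip().lower() if cls is not Group else str(value).strip().upper())
    except ValueError:
        raise RowError(row, f"unparsable {cls.__name__.lower()} value {value!r}") from None


def read_trials(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[TrialRecord]:
    """Read a delimited-text trial table into validated records.

    ``dialect`` maps canonical column names to the file's column names.
    The separator is sniffed (comma default, tab accepted) unless given.
    Row order is preserved.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (dialect or {}).items()}
    frame = frame.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return from_frame(frame)


def write_trials(trials: Sequence[TrialRecord], path: str | Path, sep: str = ",") -> None:
    to_frame(trials).to_csv(path, sep=sep, index=False)


def to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "subject_id": t.subject_id,
            "group": t.group.value,
            "session": t.session,
            "stage": t.stage.value,
            "stimulus": t.stimulus.value,
            "response": t.response.value,
            "rt": "" if t.rt is None else t.rt,
            "microarousal": int(t.microarousal),
            "n_contractions": t.n_contractions,
        })
    return pd.DataFrame(rows, columns=list(COLUMNS))


def from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        response = _parse_enum(Response, row.response, idx)
        rt_raw = str(row.rt).strip()
        rt = None if rt_raw in ("", "nan", "NA") else float(rt_raw)
        try:
            rec = TrialRecord(
                subject_id=str(row.subject_id),
                group=_parse_enum(Group, row.group, idx),
                session=int(row.session),
                stage=_parse_enum(Stage, row.stage, idx),
                stimulus=_parse_enum(Stimulus, row.stimulus, idx),
                response=response,
                rt=rt,
                microarousal=bool(int(row.microarousal)),
                n_contractions=int(row.n_contractions),
            )
        except RowError:
            raise
        except (TypeError, ValueError) as exc:
            raise RowError(idx, str(exc)) from None
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Exclusion pipeline
# ---------------------------------------------------------------------------

RULES = (
    "nonresponse", "microarousal", "single_contraction",
    "dropped_stage", "rt_bounds", "rt_outlier",
)

DEFAULT_DROP_STAGES: dict[Group, frozenset[Stage]] = {
    Group.HP: frozenset({Stage.N3, Stage.REM, Stage.LUCID_REM}),
    Group.NP: frozenset({Stage.N3}),
}


@dataclass(frozen=True)
class ExclusionConfig:
    """Trial-exclusion settings.

    rt_min/rt_max bound plausible reaction times in seconds; the outlier
    rule removes RTs beyond ``mad_multiplier`` robust deviations from the
    cell center, computed within subject x stage x stimulus cells.
    ``outlier_mode`` selects the robust reading (center = median, scale =
    1.4826 x MAD) or the literal "mean +/- 2.5 MAD" reading (center = mean,
    scale = raw MAD).
    """

    rt_min: float = 0.69
    rt_max: float = 9.9
    mad_multiplier: float = 2.5
    drop_stages: Mapping[Group, frozenset[Stage]] = field(
        default_factory=lambda: dict(DEFAULT_DROP_STAGES))
    require_multi_contraction: bool = True
    drop_microarousal: bool = True
    outlier_mode: str = "robust"   # "robust" | "literal"
    min_cell_size: int = 4         # cells smaller than this skip the outlier rule

    def __post_init__(self):
        if not (0 < self.rt_min < self.rt_max):
            raise ValueError("need 0 < rt_min < rt_max")
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be positive")
        if self.outlier_mode not in ("robust", "literal"):
            raise ValueError(f"unknown outlier_mode {self.outlier_mode!r}")


@dataclass
class ExclusionReport:
    n_input: int
    n_surviving: int
    removed_by_rule: dict[str, int]
    removed_by_rule_group: dict[str, dict[str, int]]
    all_removed: bool = False

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_surviving

    def fractions(self) -> dict[str, float]:
        if self.n_input == 0:
            return {rule: 0.0 for rule in self.removed_by_rule}
        return {rule: n / self.n_input for rule, n in self.removed_by_rule.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_input": self.n_input,
            "n_surviving": self.n_surviving,
            "n_removed": self.n_removed,
            "removed_by_rule": self.removed_by_rule,
            "removed_by_rule_group": self.removed_by_rule_group,
            "fractions": self.fractions(),
            "all_removed": self.all_removed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _outlier_bounds(rts: np.ndarray, cfg: ExclusionConfig) -> tuple[float, float]:
    if cfg.outlier_mode == "robust":
        center = float(np.median(rts))
        scale = 1.4826 * float(np.median(np.abs(rts - center)))
    else:
        center = float(np.mean(rts))
        scale = float(np.median(np.abs(rts - np.median(rts))))
    lo = center - cfg.mad_multiplier * scale
    hi = center + cfg.mad_multiplier * scale
    return lo, hi


def apply_exclusions(
    trials: Sequence[TrialRecord],
    cfg: ExclusionConfig | None = None,
) -> tuple[list[TrialRecord], ExclusionReport]:
    """Apply the trial-exclusion rules in a fixed order and tally each.

    Order: (1) non-response trials; (2) micro-arousal trials; (3) single
    muscle contractions; (4) stages dropped for the trial's group; (5) RT
    outside [rt_min, rt_max]; (6) robust RT outliers within subject x stage
    x stimulus cells. The outlier pass is iterated to a fixed point so the
    pipeline as a whole is idempotent. Each removed trial is tallied under
    the first rule that removed it.
    """
    cfg = cfg or ExclusionConfig()
    counts = {rule: 0 for rule in RULES}
    counts_group = {rule: {g.value: 0 for g in Group} for rule in RULES}

    def tally(rule: str, trial: TrialRecord) -> None:
        counts[rule] += 1
        counts_group[rule][trial.group.value] += 1

    survivors: list[TrialRecord] = []
    for t in trials:
        if t.response is Response.NONE:
            tally("nonresponse", t)
        elif cfg.drop_microarousal and t.microarousal:
            tally("microarousal", t)
        elif cfg.require_multi_contraction and t.n_contractions < 2:
            tally("single_contraction", t)
        elif t.stage in cfg.drop_stages.get(t.group, frozenset()):
            tally("dropped_stage", t)
        elif not (cfg.rt_min <= t.rt <= cfg.rt_max):
            tally("rt_bounds", t)
        else:
            survivors.append(t)

    # rule 6: per-cell robust outlier removal, iterated to a fixed point
    changed = True
    while changed:
        changed = False
        cells: dict[tuple, list[TrialRecord]] = {}
        for t in survivors:
            cells.setdefault((t.subject_id, t.stage, t.stimulus), []).append(t)
        kept: list[TrialRecord] = []
        removed_ids: set[int] = set()
        for members in cells.values():
            if len(members) < cfg.min_cell_size:
                continue
            rts = np.array([m.rt for m in members])
            lo, hi = _outlier_bounds(rts, cfg)
            for m in members:
                if not (lo <= m.rt <= hi):
                    removed_ids.add(id(m))
                    tally("rt_outlier", m)
                    changed = True
        if changed:
            survivors = [t for t in survivors if id(t) not in removed_ids]

    report = ExclusionReport(
        n_input=len(trials),
        n_surviving=len(survivors),
        removed_by_rule=counts,
        removed_by_rule_group=counts_group,
        all_removed=(len(trials) > 0 and len(survivors) == 0),
    )
    return survivors, report
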