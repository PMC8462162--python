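"""Encounter histories: construction from capture records and MARK-style I/O.

The analysis operates on session-level binary detection histories.  Nightly
captures within a trapping session collapse to a single detection; identical
history patterns are pooled with per-group (sex) counts, which is the form
the likelihood consumes and the form MARK ``.inp`` files store.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calendar import OccasionCalendar

log = logging.getLogger(__name__)

DEFAULT_GROUPS = ("F", "M")


@dataclass
class CaptureHistorySet:
    """Pooled binary encounter histories with per-group counts.

    ``histories`` is a (R, T) matrix of {0,1} distinct patterns and
    ``counts`` a (R, G) nonnegative integer matrix aligned with ``groups``.
    """

    histories: np.ndarray
    counts: np.ndarray
    groups: list[str]
    calendar: OccasionCalendar | None = None
    dropped: dict = field(default_factory=dict)

    def __post_init__(self):
        self.histories = np.asarray(self.histories, dtype=np.int8)
        if self.histories.ndim != 2:
            raise ValueError("histories must be 2-D")
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=np.int64))
        if self.counts.shape[0] != self.histories.shape[0]:
            raise ValueError("counts rows must match history rows")
        if self.counts.shape[1] != len(self.groups):
            raise ValueError("counts columns must match groups")
        if self.counts.min(initial=0) < 0:
            raise ValueError("negative counts")
        if self.histories.size and not np.isin(self.histories, (0, 1)).all():
            raise ValueError("histories must be binary")
        if self.histories.size and (self.histories.sum(axis=1) == 0).any():
            raise ValueError("all-zero history pattern retained")
        if self.calendar is not None and self.histories.shape[1] != len(self.calendar):
            raise ValueError("history length does not match calendar")

    # -- summaries ----------------------------------------------------
    @property
    def n_occasions(self) -> int:
        return self.histories.shape[1]

    @property
    def n_patterns(self) -> int:
        return self.histories.shape[0]

    def total_individuals(self, group: str | None = None) -> int:
        if group is None:
            return int(self.counts.sum())
        return int(self.counts[:, self.groups.index(group)].sum())

    def total_detections(self) -> int:
        """Number of animal-occasion detections (the default AICc ESS)."""
        return int((self.histories.sum(axis=1) * self.counts.sum(axis=1)).sum())

    # -- transforms ---------------------------------------------------
    def canonical(self) -> "CaptureHistorySet":
        """Rows sorted by pattern string, zero-count rows removed."""
        keep = self.counts.sum(axis=1) > 0
        h, c = self.histories[keep], self.counts[keep]
        keys = ["".join(map(str, row)) for row in h]
        order = np.argsort(keys)
        return CaptureHistorySet(h[order], c[order], list(self.groups), self.calendar)

    def pool_groups(self) -> "CaptureHistorySet":
        return CaptureHistorySet(
            self.histories, self.counts.sum(axis=1, keepdims=True), ["all"], self.calendar
        )

    def select_groups(self, groups: list[str]) -> "CaptureHistorySet":
        cols = [self.groups.index(g) for g in groups]
        out = CaptureHistorySet(
            self.histories, self.counts[:, cols], list(groups), self.calendar
        )
        return out.canonical()

    def equals(self, other: "CaptureHistorySet") -> bool:
        a, b = self.canonical(), other.canonical()
        return (
            a.groups == b.groups
            and a.histories.shape == b.histories.shape
            and (a.histories == b.histories).all()
            and (a.counts == b.counts).all()
        )

    @classmethod
    def from_individuals(
        cls,
        detections: np.ndarray,
        group_labels,
        groups: list[str] | None = None,
        calendar: OccasionCalendar | None = None,
    ) -> "CaptureHistorySet":
        """Pool an (n_animals, T) detection matrix into distinct patterns."""
        detections = np.asarray(detections, dtype=np.int8)
        group_labels = np.asarray(group_labels)
        seen = detections.sum(axis=1) > 0
        detections, group_labels = detections[seen], group_labels[seen]
        if groups is None:
            groups = sorted(set(group_labels.tolist()))
        keys = ["".join(map(str, row)) for row in detections]
        df = pd.DataFrame({"key": keys, "group": group_labels})
        tab = df.groupby(["key", "group"]).size().unstack(fill_value=0)
        tab = tab.reindex(columns=groups, fill_value=0).sort_index()
        hist = np.array([[int(ch) for ch in k] for k in tab.index], dtype=np.int8)
        return cls(hist, tab.to_numpy(), list(groups), calendar)


def build_histories(
    records: pd.DataFrame,
    calendar: OccasionCalendar,
    adults_only: bool = True,
    juvenile_marked: str = "keep_adult",
    unknown_sex: str = "own_group",
) -> CaptureHistorySet:
    """Build pooled encounter histories from long-format capture records.

    ``records`` needs columns ``animal_id``, ``session`` (YYYY-MM) or
    ``occasion``, ``sex`` (F/M/unknown) and ``age`` (adult/juvenile).
    Repeat captures within a session collapse to one detection.  With
    ``adults_only`` juvenile detections are removed; an animal first marked
    as a juvenile keeps its adult detections (``juvenile_marked='keep_adult'``)
    or is dropped entirely (``'drop_animal'``).  Unknown sex either forms its
    own group (default, with a warning) or is dropped.
    """
    df = records.copy()
    if "occasion" not in df.columns:
        df["occasion"] = [calendar.occasion_of_date(s) for s in df["session"]]
    else:
        bad = ~df["occasion"].isin(range(1, len(calendar) + 1))
        if bad.any():
            raise ValueError(f"records reference unknown occasions: "
                             f"{sorted(df.loc[bad, 'occasion'].unique())}")
    df["sex"] = df.get("sex", "unknown")
    df["sex"] = df["sex"].fillna("unknown")
    dropped: dict[str, int] = {}

    if unknown_sex == "drop":
        n_unk = df.loc[df["sex"] == "unknown", "animal_id"].nunique()
        if n_unk:
            dropped["unknown_sex_animals"] = n_unk
        df = df[df["sex"] != "unknown"]
    elif (df["sex"] == "unknown").any():
        log.warning(
            "%d records with unknown sex kept as their own group",
            int((df["sex"] == "unknown").sum()),
        )

    if adults_only:
        if juvenile_marked == "drop_animal":
            juvie_ids = set(df.loc[df["age"] == "juvenile", "animal_id"])
            dropped["juvenile_marked_animals"] = len(juvie_ids)
            df = df[~df["animal_id"].isin(juvie_ids)]
        else:
            before = df["animal_id"].nunique()
            df = df[df["age"] != "juvenile"]
            dropped["juvenile_only_animals"] = before - df["animal_id"].nunique()

    if df.empty:
        raise ValueError("no records remain after filtering")

    sexes = df.groupby("animal_id")["sex"].first()
    ids = sexes.index.to_numpy()
    id_pos = {a: i for i, a in enumerate(ids)}
    det = np.zeros((len(ids), len(calendar)), dtype=np.int8)
    for aid, occ in zip(df["animal_id"], df["occasion"]):
        det[id_pos[aid], occ - 1] = 1

    groups = [g for g in ("F", "M", "unknown") if g in set(sexes)]
    out = CaptureHistorySet.from_individuals(
        det, sexes.to_numpy(), groups=groups, calendar=calendar
    )
    out.dropped = dropped
    return out


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str})
    required = {"animal_id", "session", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"record CSV missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# MARK .inp dialect: "<binary history> <freq_g1> ... <freq_gG> ;" per line,
# /* ... */ comments allowed anywhere.
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"/\*.*?\*/", re.DOTALL)


def read_inp(
    path, group_count: int = 1, calendar: OccasionCalendar | None = None
) -> CaptureHistorySet:
    """Parse a MARK-style encounter-history file."""
    with open(path) as fh:
        raw = fh.read()
    # map to line numbers before stripping comments
    text = _COMMENT_RE.sub(lambda m: re.sub(r"[^\n]", " ", m.group()), raw)
    patterns, counts = [], []
    length = None
    pending = ""
    for lineno, line in enumerate(text.splitlines(), start=1):
        pending += " " + line
        if ";" not in pending:
            continue
        for stmt in pending.split(";")[:-1]:
            stmt = stmt.strip()
            if not stmt:
                continue
            toks = stmt.split()
            if len(toks) != 1 + group_count:
                raise ValueError(
                    f"{path}:{lineno}: expected history + {group_count} "
                    f"frequencies, got {len(toks)} tokens"
                )
            hist = toks[0]
            if not set(hist) <= {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: non-binary history {hist!r}")
            if length is None:
                length = len(hist)
            elif len(hist) != length:
                raise ValueError(
                    f"{path}:{lineno}: ragged history length "
                    f"({len(hist)} != {length})"
                )
            try:
                freqs = [int(t) for t in toks[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad frequency in {stmt!r}") from exc
            if any(f < 0 for f in freqs):
                raise ValueError(f"{path}:{lineno}: negative frequency")
            patterns.append([int(c) for c in hist])
            counts.append(freqs)
        pending = pending.rsplit(";", 1)[-1]
    if pending.strip():
        raise ValueError(f"{path}: trailing statement without ';': {pending.strip()!r}")
    groups = [f"g{i + 1}" for i in range(group_count)]
    if group_count == 2:
        groups = list(DEFAULT_GROUPS)
    if not patterns:
        return CaptureHistorySet(
            np.zeros((0, len(calendar) if calendar else 0), dtype=np.int8),
            np.zeros((0, group_count), dtype=np.int64),
            groups,
            calendar,
        )
    out = CaptureHistorySet(
        np.array(patterns, dtype=np.int8),
        np.array(counts, dtype=np.int64),
        groups,
        calendar,
    )
    return out.canonical()


def write_inp(chs: CaptureHistorySet, path) -> None:
    """Write histories in the MARK dialect; read_inp round-trips exactly."""
    chs = chs.canonical()
    with open(path, "w") as fh:
        fh.write(
            f"/* encounter histories: T={chs.n_occasions}, "
            f"groups={','.join(chs.groups)} */\n"
        )
        for row, cnt in zip(chs.histories, chs.counts):
            fh.write("".join(map(str, row)) + " " + " ".join(map(str, cnt)) + ";\n")
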