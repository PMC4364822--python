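"""Capture-history data model, file I/O, and the dataset reconstruction.

A capture history is one row per tagged individual and one column per
sampling occasion, coded

* ``PRE``  (CSV ``.``)  -- occasion before the individual's release,
* ``0``                 -- at risk but not detected,
* ``1``                 -- detected alive (the release itself is the
  0th capture and is coded 1),
* ``2``                 -- recovered dead (shell located by its PIT tag),
* ``POST`` (CSV ``x``)  -- occasion after a dead recovery (censored).

The study's individual-level histories were never published; only the
per-occasion aggregate release / live-recapture / dead-recovery counts are
available.  :func:`reconstruct_dataset` builds the canonical completion of
those aggregates under the minimal-miss rule: a live-detection deficit is a
temporary miss only when the individual is detected again later, otherwise
it is a permanent disappearance (death at the earliest consistent
interval), and events are assigned to the lowest-index individuals of the
earliest eligible cohort.  Under the non-hierarchical likelihoods
individuals within a cohort are exchangeable, so only the pattern counts
matter and the fixed assignment just makes the output deterministic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .design import CohortTable, OccasionCalendar, powell_river_design

PRE = -1
NOT_SEEN = 0
SEEN = 1
DEAD_RECOVERY = 2
POST = 3

_CODE_TO_CHAR = {PRE: ".", NOT_SEEN: "0", SEEN: "1", DEAD_RECOVERY: "2", POST: "x"}
_CHAR_TO_CODE = {v: k for k, v in _CODE_TO_CHAR.items()}


class HistoryError(ValueError):
    """A capture-history row or set violates the coding invariants."""


class ReconstructionError(ValueError):
    """Aggregate counts admit no consistent capture-history completion."""


def parse_history(text: str, release_occasion: int, n_occasions: int | None = None) -> np.ndarray:
    """Parse a whitespace-separated history string into a coded row.

    ``text`` covers occasions from ``release_occasion`` (0-based) onward;
    occasions before release are filled with ``PRE``.  Tokens after a dead
    recovery must be ``0`` and are recoded ``POST``.  With ``n_occasions``
    the row is padded with ``POST`` after a recovery up to full length.

    >>> parse_history("1 0 1", release_occasion=1).tolist()
    [-1, 1, 0, 1]
    """
    tokens = text.split()
    if not tokens:
        raise HistoryError("empty history string")
    codes = []
    for tok in tokens:
        if tok not in ("0", "1", "2"):
            raise HistoryError(f"bad history token {tok!r} (expected 0, 1 or 2)")
        codes.append(int(tok))
    if release_occasion < 0:
        raise HistoryError("release occasion must be non-negative")
    row = np.full(release_occasion + len(codes), PRE, dtype=np.int8)
    row[release_occasion:] = codes
    dead_at = np.flatnonzero(row == DEAD_RECOVERY)
    if dead_at.size > 1:
        raise HistoryError("more than one dead recovery in a history")
    if dead_at.size == 1:
        r = int(dead_at[0])
        tail = row[r + 1 :]
        if np.any(tail == SEEN):
            raise HistoryError("live detection after a dead recovery")
        row[r + 1 :] = POST
    if n_occasions is not None:
        if row.size > n_occasions:
            raise HistoryError("history longer than the calendar")
        pad = np.full(n_occasions - row.size, POST if dead_at.size else NOT_SEEN, np.int8)
        row = np.concatenate([row, pad])
    return row


def format_history(row: np.ndarray) -> str:
    """Inverse of :func:`parse_history`: codes from release to recovery."""
    row = np.asarray(row)
    start = int(np.argmax(row != PRE))
    out = []
    for c in row[start:]:
        if c == POST:
            break
        out.append(_CODE_TO_CHAR[int(c)])
    return " ".join(out)


@dataclass(frozen=True)
class CaptureHistorySet:
    """Coded detection matrix with per-individual release occasions."""

    codes: np.ndarray  # (n, K) int8
    release: np.ndarray  # (n,) 0-based occasion index
    ids: tuple[str, ...]
    calendar: OccasionCalendar

    def __post_init__(self):
        object.__setattr__(self, "codes", np.asarray(self.codes, np.int8))
        object.__setattr__(self, "release", np.asarray(self.release, int))
        self.validate()

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.codes.shape[1]

    def validate(self) -> None:
        n, k = self.codes.shape
        if k != self.calendar.n_occasions:
            raise HistoryError("history width does not match the calendar")
        if self.release.shape != (n,) or len(self.ids) != n:
            raise HistoryError("ids/release length does not match the matrix")
        if len(set(self.ids)) != n:
            raise HistoryError("duplicate individual ids")
        bad = []
        for i in range(n):
            row, rel = self.codes[i], int(self.release[i])
            if not 0 <= rel < k:
                bad.append((self.ids[i], "release occasion outside calendar"))
                continue
            if np.any(row[:rel] != PRE) or np.any(row[rel:] == PRE):
                bad.append((self.ids[i], "PRE codes must exactly precede release"))
            if row[rel] != SEEN:
                bad.append((self.ids[i], "release occasion must be coded 1"))
            dead = np.flatnonzero(row == DEAD_RECOVERY)
            if dead.size > 1:
                bad.append((self.ids[i], "more than one dead recovery"))
            elif dead.size == 1:
                r = int(dead[0])
                if np.any(row[r + 1 :] != POST):
                    bad.append((self.ids[i], "codes after a dead recovery must be POST"))
            if dead.size == 0 and np.any(row == POST):
                bad.append((self.ids[i], "POST without a dead recovery"))
        if bad:
            msg = "; ".join(f"{i}: {why}" for i, why in bad[:10])
            raise HistoryError(f"invalid capture histories ({len(bad)} rows): {msg}")

    # -- derived per-row quantities used throughout the likelihoods --------

    def last_seen_alive(self) -> np.ndarray:
        """Last occasion coded 1 per row (release counts as seen)."""
        seen = self.codes == SEEN
        return (self.n_occasions - 1) - np.argmax(seen[:, ::-1], axis=1)

    def recovery_occasion(self) -> np.ndarray:
        """Occasion of the dead recovery per row, or -1."""
        isdead = self.codes == DEAD_RECOVERY
        out = np.where(isdead.any(axis=1), np.argmax(isdead, axis=1), -1)
        return out.astype(int)

    def subset(self, index) -> "CaptureHistorySet":
        index = np.asarray(index)
        return CaptureHistorySet(
            self.codes[index],
            self.release[index],
            tuple(np.asarray(self.ids, object)[index]),
            self.calendar,
        )


@dataclass(frozen=True)
class AggregateCounts:
    """Per-occasion release, live-recapture and dead-recovery tallies."""

    released: np.ndarray
    live_recaptured: np.ndarray
    dead_recaptured: np.ndarray

    def __post_init__(self):
        for name in ("released", "live_recaptured", "dead_recaptured"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), int))
        k = self.released.size
        if self.live_recaptured.size != k or self.dead_recaptured.size != k:
            raise ValueError("aggregate rows must have equal length")
        if min(self.released.min(), self.live_recaptured.min(), self.dead_recaptured.min()) < 0:
            raise ValueError("aggregate counts must be non-negative")
        cum = np.cumsum(self.released)
        at_risk = np.concatenate([[0], cum[:-1]])
        if np.any(self.live_recaptured > at_risk):
            k_bad = int(np.argmax(self.live_recaptured > at_risk))
            raise ValueError(
                f"live recaptures exceed prior releases at occasion {k_bad + 1}"
            )

    @property
    def n_occasions(self) -> int:
        return self.released.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "occasion": np.arange(1, self.n_occasions + 1),
                "released": self.released,
                "live_recaptured": self.live_recaptured,
                "dead_recaptured": self.dead_recaptured,
            }
        )


def powell_river_aggregates() -> AggregateCounts:
    """The study's published per-occasion aggregate counts."""
    return AggregateCounts(
        released=[23, 28, 38, 9, 1, 0, 0, 0],
        live_recaptured=[0, 23, 50, 88, 97, 96, 95, 94],
        dead_recaptured=[0, 0, 0, 0, 1, 0, 0, 0],
    )


def tabulate_counts(hset: CaptureHistorySet) -> AggregateCounts:
    """Per-occasion tallies of releases, live recaptures and dead recoveries.

    The code-1 entry at an individual's release occasion is a release, not
    a recapture, and is excluded from the live-recapture row.
    """
    n, k = hset.codes.shape
    released = np.bincount(hset.release, minlength=k)
    karr = np.arange(k)
    live = ((hset.codes == SEEN) & (karr[None, :] > hset.release[:, None])).sum(axis=0)
    dead = (hset.codes == DEAD_RECOVERY).sum(axis=0)
    return AggregateCounts(released, live, dead)


def _minimal_miss_schedule(agg: AggregateCounts):
    """Solve the minimal-miss completion at the level of per-occasion counts.

    Returns ``(alive, misses, deaths_unrecovered)`` where ``alive[k]`` is
    the smallest number of individuals (released at or before k) alive at
    occasion k consistent with all later counts, ``misses[k]`` the forced
    number of undetected-but-alive individuals at k, and
    ``deaths_unrecovered[k]`` the unrecovered deaths in the interval ending
    at k.  Recovered-dead individuals die in the interval immediately
    before their recovery (the latest time consistent with the counts).
    """
    rel, live, dead = agg.released, agg.live_recaptured, agg.dead_recaptured
    k = agg.n_occasions
    cum_rel = np.cumsum(rel)
    cum_dead = np.cumsum(dead)
    alive = np.zeros(k, int)
    alive[k - 1] = live[k - 1] + rel[k - 1]
    for j in range(k - 2, -1, -1):
        alive[j] = max(live[j] + rel[j], alive[j + 1] - rel[j + 1] + dead[j + 1])
        if alive[j] > cum_rel[j] - cum_dead[j]:
            raise ReconstructionError(
                f"counts at occasion {j + 1} require more live individuals than exist"
            )
    misses = alive - rel - live
    if np.any(misses < 0):
        j = int(np.argmax(misses < 0))
        raise ReconstructionError(f"inconsistent live count at occasion {j + 1}")
    deaths_unrec = np.zeros(k, int)
    for j in range(1, k):
        total = alive[j - 1] + rel[j] - alive[j]
        deaths_unrec[j] = total - dead[j]
        if deaths_unrec[j] < 0:
            raise ReconstructionError(
                f"more dead recoveries than deaths in the interval ending at occasion {j + 1}"
            )
    return alive, misses, deaths_unrec


def reconstruct_dataset(
    agg: AggregateCounts,
    calendar: OccasionCalendar,
    cohorts: CohortTable,
    id_prefix: str = "m",
) -> CaptureHistorySet:
    """Canonical minimal-miss capture-history completion of aggregate counts.

    The result is deterministic: its per-occasion tallies reproduce ``agg``
    exactly (:func:`tabulate_counts` is the inverse), and each miss or
    death event is assigned to the lowest-index not-yet-assigned individual
    of the earliest cohort released before the event's occasion.
    """
    k = calendar.n_occasions
    if agg.n_occasions != k:
        raise ReconstructionError("aggregate rows do not match the calendar")
    if np.any(cohorts.releases_per_occasion(k) != agg.released):
        raise ReconstructionError("cohort table disagrees with the release row")

    _, misses, deaths_unrec = _minimal_miss_schedule(agg)

    n = cohorts.n_individuals
    release = np.repeat(cohorts.release_occasion, cohorts.cohort_size)
    order = np.argsort(release, kind="stable")  # earliest cohort first
    release = release[order]
    width = max(3, len(str(n)))
    ids = tuple(f"{id_prefix}{i + 1:0{width}d}" for i in range(n))

    codes = np.full((n, k), PRE, dtype=np.int8)
    for i in range(n):
        codes[i, release[i] :] = SEEN

    assigned = np.zeros(n, bool)

    def take(occ: int, count: int) -> list[int]:
        """Lowest-index unassigned individuals released before ``occ``."""
        picked = [
            i for i in range(n) if not assigned[i] and release[i] < occ
        ][:count]
        if len(picked) < count:
            raise ReconstructionError(
                f"not enough eligible individuals for the events at occasion {occ + 1}"
            )
        for i in picked:
            assigned[i] = True
        return picked

    for occ in range(1, k):
        for i in take(occ, int(misses[occ])):
            codes[i, occ] = NOT_SEEN
        for i in take(occ, int(agg.dead_recaptured[occ])):
            codes[i, occ] = DEAD_RECOVERY
            codes[i, occ + 1 :] = POST
        for i in take(occ, int(deaths_unrec[occ])):
            codes[i, occ:] = NOT_SEEN

    hset = CaptureHistorySet(codes, release, ids, calendar)
    check = tabulate_counts(hset)
    for name in ("released", "live_recaptured", "dead_recaptured"):
        if np.any(getattr(check, name) != getattr(agg, name)):
            raise ReconstructionError(f"internal error: {name} tallies not reproduced")
    return hset


def reconstruct_study_dataset(season_rule: str = "majority") -> CaptureHistorySet:
    """The canonical reconstruction of the Powell River dataset."""
    calendar, cohorts = powell_river_design(season_rule)
    return reconstruct_dataset(powell_river_aggregates(), calendar, cohorts)


def write_histories(hset: CaptureHistorySet, path) -> None:
    """Write a capture-history CSV (id, release_occasion, o1..oK).

    Occasion numbers in the file are 1-based; cell characters are
    ``. 0 1 2 x`` for PRE / not seen / seen / dead recovery / censored.
    """
    k = hset.n_occasions
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "release_occasion"] + [f"o{j}" for j in range(1, k + 1)])
        for i in range(hset.n_individuals):
            row = [_CODE_TO_CHAR[int(c)] for c in hset.codes[i]]
            w.writerow([hset.ids[i], int(hset.release[i]) + 1] + row)


def read_histories(path, calendar: OccasionCalendar) -> CaptureHistorySet:
    """Read a capture-history CSV written by :func:`write_histories`."""
    ids, release, rows = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        k = len(header) - 2
        if header[:2] != ["id", "release_occasion"]:
            raise HistoryError("unexpected capture-history CSV header")
        for line in reader:
            ids.append(line[0])
            release.append(int(line[1]) - 1)
            try:
                rows.append([_CHAR_TO_CODE[c] for c in line[2:]])
            except KeyError as err:
                raise HistoryError(f"bad cell value {err} in row {line[0]}") from None
            if len(line) - 2 != k:
                raise HistoryError(f"row {line[0]} has wrong width")
    codes = np.array(rows, np.int8) if rows else np.empty((0, k), np.int8)
    return CaptureHistorySet(codes, np.asarray(release, int), tuple(ids), calendar)


def write_counts(agg: AggregateCounts, path) -> None:
    agg.to_frame().to_csv(path, index=False)


def read_counts(path) -> AggregateCounts:
    import pandas as pd

    df = pd.read_csv(path)
    return AggregateCounts(
        df["released"].to_numpy(),
        df["live_recaptured"].to_numpy(),
        df["dead_recaptured"].to_numpy(),
    )
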