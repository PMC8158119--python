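"""Study-by-acupoint incidence corpus: data model, CSV I/O and screening arithmetic.

The corpus is a binary incidence table: one row per clinical study, one
column per acupoint, a mark where the study's prescription includes the
point.  The packaged fixture transcribes the 13-study / 27-acupoint table
assembled from a systematic review of acupuncture for poor ovarian
response; it is shipped as a plain CSV asset so it can be audited cell by
cell against the printed source.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Recognised treatment modality labels.
MODALITIES = ("acupuncture", "electro-acupuncture", "TEAS")

_CODE_RE = re.compile(r"^[A-Z]{1,4}(?:-[A-Z]{1,3})?\d{1,3}$")


def normalize_code(raw_label: str) -> str:
    """Normalize an acupoint label: uppercase, strip internal whitespace.

    Hyphens are preserved ("EX-CA1" stays "EX-CA1"); printed labels such as
    "SP 6" or "EX-B 8" collapse to "SP6" / "EX-B8".  Idempotent.

    Raises
    ------
    ValidationError
        If the label is empty or whitespace-only.
    """
    if raw_label is None or not str(raw_label).strip():
        raise ValidationError("acupoint label is empty or whitespace-only")
    return re.sub(r"\s+", "", str(raw_label)).upper()


def is_valid_code(code: str) -> bool:
    """True if ``code`` looks like a normalized acupoint code (e.g. CV4, EX-CA1)."""
    return bool(_CODE_RE.match(code))


@dataclass(frozen=True)
class StudyRecord:
    """One source study: its label, treatment modality and acupoint set."""

    study_id: str
    modality: str
    acupoints: frozenset[str]

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"unknown modality {self.modality!r} for study {self.study_id!r}; "
                f"expected one of {MODALITIES}"
            )
        if not self.acupoints:
            raise ValidationError(f"study {self.study_id!r} has no acupoint marks")


@dataclass(frozen=True)
class ScreeningFlow:
    """PRISMA-style record screening counts with their arithmetic identities."""

    identified: int
    excluded_screening: int
    fulltext: int
    excluded_fulltext: int
    included: int

    def __post_init__(self) -> None:
        counts = (self.identified, self.excluded_screening, self.fulltext,
                  self.excluded_fulltext, self.included)
        if any(c < 0 for c in counts):
            raise ValidationError(f"screening counts must be non-negative, got {counts}")
        if self.fulltext != self.identified - self.excluded_screening:
            raise ValidationError("fulltext must equal identified - excluded_screening")
        if self.included != self.fulltext - self.excluded_fulltext:
            raise ValidationError("included must equal fulltext - excluded_fulltext")


def prisma_flow(identified: int, excluded_screening: int,
                excluded_fulltext: int) -> ScreeningFlow:
    """Complete the screening-flow arithmetic from the three printed counts."""
    fulltext = identified - excluded_screening
    if fulltext < 0:
        raise ValidationError(
            f"excluded_screening ({excluded_screening}) exceeds identified ({identified})"
        )
    included = fulltext - excluded_fulltext
    if included < 0:
        raise ValidationError(
            f"excluded_fulltext ({excluded_fulltext}) exceeds fulltext ({fulltext})"
        )
    return ScreeningFlow(identified, excluded_screening, fulltext,
                         excluded_fulltext, included)


class OccurrenceMatrix:
    """Validated binary study-by-acupoint incidence matrix.

    Parameters
    ----------
    studies
        Ordered study records; ids must be unique.
    acupoints
        Ordered, normalized acupoint codes.  The order is meaningful: it is
        the deterministic tie-breaking order used downstream, and for the
        packaged fixture it is the printed row (meridian) order.
    incidence
        ``(n_studies, n_acupoints)`` array of 0/1 marks.
    """

    def __init__(self, studies: list[StudyRecord], acupoints: list[str],
                 incidence: np.ndarray) -> None:
        self.studies = list(studies)
        self.acupoints = [normalize_code(a) for a in acupoints]
        self.incidence = np.asarray(incidence, dtype=int)
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: list[StudyRecord],
                     acupoint_order: list[str] | None = None) -> "OccurrenceMatrix":
        """Build the matrix from study records, columns in ``acupoint_order``
        (default: order of first appearance across studies)."""
        if acupoint_order is None:
            acupoint_order = []
            seen = set()
            for rec in records:
                for a in sorted(rec.acupoints):
                    if a not in seen:
                        seen.add(a)
                        acupoint_order.append(a)
        idx = {a: j for j, a in enumerate(acupoint_order)}
        inc = np.zeros((len(records), len(acupoint_order)), dtype=int)
        for i, rec in enumerate(records):
            for a in rec.acupoints:
                inc[i, idx[a]] = 1
        return cls(records, acupoint_order, inc)

    def _validate(self) -> None:
        n_s, n_a = self.incidence.shape
        if n_s != len(self.studies) or n_a != len(self.acupoints):
            raise ValidationError("incidence shape does not match study/acupoint lists")
        if len({s.study_id for s in self.studies}) != n_s:
            raise ValidationError("duplicate study_id in corpus")
        if len(set(self.acupoints)) != n_a:
            raise ValidationError("duplicate acupoint code in corpus")
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValidationError("incidence values must be 0 or 1")
        empty_rows = [self.studies[i].study_id
                      for i in np.flatnonzero(self.incidence.sum(axis=1) == 0)]
        if empty_rows:
            raise ValidationError(f"studies with zero acupoint marks: {empty_rows}")
        empty_cols = [self.acupoints[j]
                      for j in np.flatnonzero(self.incidence.sum(axis=0) == 0)]
        if empty_cols:
            raise ValidationError(f"acupoints never marked: {empty_cols}")
        for i, rec in enumerate(self.studies):
            marked = {self.acupoints[j] for j in np.flatnonzero(self.incidence[i])}
            if marked != set(rec.acupoints):
                raise ValidationError(
                    f"incidence row disagrees with record for {rec.study_id!r}"
                )

    # -- accessors --------------------------------------------------------

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_acupoints(self) -> int:
        return len(self.acupoints)

    @property
    def frequencies(self) -> pd.Series:
        """Marginal study count f_i per acupoint, in matrix column order."""
        return pd.Series(self.incidence.sum(axis=0), index=self.acupoints, name="f")

    def modality_counts(self) -> dict[str, int]:
        counts = {m: 0 for m in MODALITIES}
        for s in self.studies:
            counts[s.modality] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Incidence as a DataFrame (studies x acupoints)."""
        return pd.DataFrame(self.incidence,
                            index=[s.study_id for s in self.studies],
                            columns=self.acupoints)

    def equals(self, other: "OccurrenceMatrix") -> bool:
        """Content equality under row/column alignment (order-insensitive)."""
        if {s.study_id for s in self.studies} != {s.study_id for s in other.studies}:
            return False
        if set(self.acupoints) != set(other.acupoints):
            return False
        mine = self.to_frame().sort_index().sort_index(axis=1)
        theirs = other.to_frame().sort_index().sort_index(axis=1)
        mods_mine = {s.study_id: s.modality for s in self.studies}
        mods_theirs = {s.study_id: s.modality for s in other.studies}
        return mine.equals(theirs) and mods_mine == mods_theirs


# -- CSV I/O --------------------------------------------------------------

def load_occurrence(path: str | Path, format: str = "wide") -> OccurrenceMatrix:
    """Read an occurrence matrix from CSV.

    ``wide``: columns ``study_id,modality,<code>,<code>,...`` with 0/1 cells;
    column order defines the matrix acupoint order.
    ``long``: columns ``study_id,modality,acupoint``, one mark per row;
    acupoint order is order of first appearance.  Duplicate marks collapse
    with a logged warning.
    """
    path = Path(path)
    if format == "wide":
        df = pd.read_csv(path, dtype=str)
        if list(df.columns[:2]) != ["study_id", "modality"]:
            raise ValidationError(
                f"wide CSV must start with study_id,modality columns, got {list(df.columns[:2])}"
            )
        codes = [normalize_code(c) for c in df.columns[2:]]
        records = []
        inc_rows = []
        for _, row in df.iterrows():
            marks = np.array([int(row[c]) for c in df.columns[2:]])
            points = frozenset(codes[j] for j in np.flatnonzero(marks))
            records.append(StudyRecord(str(row["study_id"]), str(row["modality"]), points))
            inc_rows.append(marks)
        return OccurrenceMatrix(records, codes, np.array(inc_rows))
    if format == "long":
        df = pd.read_csv(path, dtype=str)
        required = {"study_id", "modality", "acupoint"}
        if not required.issubset(df.columns):
            raise ValidationError(f"long CSV must have columns {sorted(required)}")
        df = df.assign(acupoint=df["acupoint"].map(normalize_code))
        dups = df.duplicated(subset=["study_id", "acupoint"])
        if dups.any():
            logger.warning("collapsing %d duplicate (study, acupoint) marks", dups.sum())
            df = df[~dups]
        order: list[str] = []
        for a in df["acupoint"]:
            if a not in order:
                order.append(a)
        records = []
        for sid, grp in df.groupby("study_id", sort=False):
            mods = grp["modality"].unique()
            if len(mods) > 1:
                raise ValidationError(f"study {sid!r} has conflicting modality labels")
            records.append(StudyRecord(str(sid), str(mods[0]), frozenset(grp["acupoint"])))
        return OccurrenceMatrix.from_records(records, acupoint_order=order)
    raise ValidationError(f"unknown occurrence format {format!r}")


def write_occurrence(m: OccurrenceMatrix, path: str | Path, format: str = "wide") -> None:
    """Write the matrix back to CSV in either dialect (inverse of load_occurrence)."""
    path = Path(path)
    if format == "wide":
        df = m.to_frame()
        df.insert(0, "modality", [s.modality for s in m.studies])
        df.index.name = "study_id"
        df.to_csv(path)
    elif format == "long":
        rows = []
        for i, s in enumerate(m.studies):
            for j, a in enumerate(m.acupoints):
                if m.incidence[i, j]:
                    rows.append((s.study_id, s.modality, a))
        pd.DataFrame(rows, columns=["study_id", "modality", "acupoint"]).to_csv(
            path, index=False)
    else:
        raise ValidationError(f"unknown occurrence format {format!r}")


def builtin_table2() -> OccurrenceMatrix:
    """The packaged 13-study / 27-acupoint incidence table.

    Transcribed from the published summary of the systematic review;
    acupoint (column-to-row) order follows the printed meridian order and
    study order follows the printed column groups, which also fix the
    modality assignment (4 acupuncture, 5 electro-acupuncture, 4 TEAS).
    """
    with resources.as_file(resources.files("acunet.data") / "table2.csv") as p:
        return load_occurrence(p, format="wide")


def marginal_frequencies(m: OccurrenceMatrix) -> pd.DataFrame:
    """Per-acupoint marginal frequency table, sorted by descending f then code.

    Columns: ``acupoint``, ``f`` (number of studies using the point), and
    ``proportion`` (f / N).
    """
    f = m.frequencies
    out = pd.DataFrame({"acupoint": f.index, "f": f.values,
                        "proportion": f.values / m.n_studies})
    return out.sort_values(["f", "acupoint"], ascending=[False, True],
                           ignore_index=True)
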