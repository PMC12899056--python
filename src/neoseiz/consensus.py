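"""Majority-vote labeling, the annotation disagreement rate, and subject selection.

Three experts annotate each second 0/1. A second is consensus-positive when
at least two experts mark it; it counts as disagreement when the expert sum
is 1 or 2 (not unanimous). A subject's ADR is the percentage of annotated
seconds in disagreement, and cohort selection keeps the k lowest-ADR
subjects per clinical group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationSet",
    "ConsensusTrack",
    "consensus_per_second",
    "compute_adr",
    "select_subjects",
    "read_annotations_csv",
    "write_selection_report",
    "UndefinedADRError",
    "SelectionError",
]


class UndefinedADRError(ValueError):
    pass


class SelectionError(ValueError):
    pass


@dataclass
class AnnotationSet:
    subject_id: str
    annotations: np.ndarray  # 3 x T_seconds, binary

    def __post_init__(self):
        self.annotations = np.asarray(self.annotations)
        if self.annotations.ndim != 2 or self.annotations.shape[0] != 3:
            raise ValueError("annotations must be a 3 x T_seconds matrix")
        if not np.isin(self.annotations, (0, 1)).all():
            raise ValueError("annotations must contain only 0/1 entries")
        self.annotations = self.annotations.astype(np.int8)

    @property
    def t_seconds(self) -> int:
        return self.annotations.shape[1]


@dataclass
class ConsensusTrack:
    consensus: np.ndarray      # 1 where expert sum >= 2
    disagreement: np.ndarray   # 1 where expert sum in {1, 2}


def consensus_per_second(ann: AnnotationSet) -> ConsensusTrack:
    sums = ann.annotations.sum(axis=0)
    return ConsensusTrack(consensus=(sums >= 2).astype(np.int8),
                          disagreement=((sums == 1) | (sums == 2)).astype(np.int8))


def compute_adr(ann: AnnotationSet) -> float:
    """Percent of annotated seconds on which the three experts are not unanimous."""
    if ann.t_seconds == 0:
        raise UndefinedADRError(f"subject {ann.subject_id!r} has no annotated seconds")
    track = consensus_per_second(ann)
    return 100.0 * float(track.disagreement.sum()) / ann.t_seconds


def select_subjects(selection_input: list[tuple[AnnotationSet, str]],
                    k_per_group: int) -> pd.DataFrame:
    """Rank subjects by ascending ADR within each group and keep the k lowest.

    Ties are broken by lexicographic subject_id. Returns one row per subject:
    (subject_id, group, t_total, t_disagreement, adr, selected).
    """
    rows = []
    for ann, group in selection_input:
        track = consensus_per_second(ann)
        rows.append({
            "subject_id": ann.subject_id,
            "group": group,
            "t_total": ann.t_seconds,
            "t_disagreement": int(track.disagreement.sum()),
            "adr": compute_adr(ann),
        })
    df = pd.DataFrame(rows)
    df["selected"] = False
    for group, sub in df.groupby("group"):
        if len(sub) < k_per_group:
            raise SelectionError(f"group {group!r} has only {len(sub)} subjects, "
                                 f"need {k_per_group}")
        keep = sub.sort_values(["adr", "subject_id"]).head(k_per_group).index
        df.loc[keep, "selected"] = True
    return df.sort_values(["group", "adr", "subject_id"]).reset_index(drop=True)


def read_annotations_csv(path) -> dict[str, AnnotationSet]:
    """Read (subject_id, second_index, expert1..3) rows into AnnotationSets."""
    df = pd.read_csv(path)
    out: dict[str, AnnotationSet] = {}
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("second_index")
        expected = np.arange(len(sub))
        if not np.array_equal(sub["second_index"].to_numpy(), expected):
            raise ValueError(f"subject {sid!r}: second_index must be 0..T-1 contiguous")
        mat = sub[["expert1", "expert2", "expert3"]].to_numpy().T
        out[str(sid)] = AnnotationSet(subject_id=str(sid), annotations=mat)
    return out


def write_selection_report(df: pd.DataFrame, path) -> None:
    """Table-style selection report (SampleID, Ttotal, Tdisagreement, ADR, Selected)."""
    report = pd.DataFrame({
        "SampleID": df["subject_id"],
        "Group": df["group"],
        "Ttotal": df["t_total"],
        "Tdisagreement": df["t_disagreement"],
        "ADR": df["adr"].round(2),
        "Selected": df["selected"],
    })
    report.to_csv(path, index=False)
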