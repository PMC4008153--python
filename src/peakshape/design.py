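"""Experiment design: samples, conditions, contrast and replicate null pairs.

The testing procedure needs two ingredients from the design: which
sample pairs span the tested contrast (group A vs group B), and which
pairs differ only by biological/technical variability (the *null
pairs*, typically replicate pairs within a condition) from which the
empirical null distribution of the statistic is built.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from peakshape.errors import InvalidInputError

__all__ = ["ExperimentDesign"]


def _as_conditions(spec) -> tuple[str, ...]:
    if isinstance(spec, str):
        return (spec,)
    return tuple(str(c) for c in spec)


@dataclass(frozen=True)
class ExperimentDesign:
    """Samples with condition labels, a contrast and declared null pairs.

    Parameters
    ----------
    samples:
        Sequence of ``(sample_id, condition, source_ref)`` triples;
        ``source_ref`` is a file path or None for in-memory sources.
    contrast:
        ``(conditions_A, conditions_B)``; each side a condition label or
        a sequence of labels.
    null_pairs:
        Sample-id pairs declared to differ only by biological/technical
        variability (usually replicate pairs within one condition).
    """

    samples: tuple
    contrast: tuple
    null_pairs: tuple

    def __init__(self, samples, contrast, null_pairs):
        samples = tuple((str(s), str(c), f) for s, c, f in samples)
        contrast = (_as_conditions(contrast[0]), _as_conditions(contrast[1]))
        null_pairs = tuple((str(a), str(b)) for a, b in null_pairs)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "contrast", contrast)
        object.__setattr__(self, "null_pairs", null_pairs)
        self._validate()

    def _validate(self) -> None:
        ids = [s for s, _, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("sample ids must be unique")
        known = set(ids)
        for a, b in self.null_pairs:
            if a not in known or b not in known:
                raise InvalidInputError(f"null pair ({a}, {b}) references unknown sample")
            if a == b:
                raise InvalidInputError(f"null pair ({a}, {b}) repeats one sample")
        if not self.null_pairs:
            raise InvalidInputError("at least one null pair is required")
        if not self.group_a_samples or not self.group_b_samples:
            raise InvalidInputError(
                "both contrast groups must contain at least one sample"
            )

    def _group(self, conditions: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(s for s, c, _ in self.samples if c in conditions)

    @property
    def group_a_samples(self) -> tuple[str, ...]:
        return self._group(self.contrast[0])

    @property
    def group_b_samples(self) -> tuple[str, ...]:
        return self._group(self.contrast[1])

    @property
    def involved_samples(self) -> tuple[str, ...]:
        """Samples entering the contrast or a null pair, in design order."""
        used = set(self.group_a_samples) | set(self.group_b_samples)
        for a, b in self.null_pairs:
            used.update((a, b))
        return tuple(s for s, _, _ in self.samples if s in used)

    @property
    def between_pairs(self) -> tuple[tuple[str, str], ...]:
        """All (group A sample, group B sample) pairs of the contrast."""
        return tuple(
            (a, b) for a in self.group_a_samples for b in self.group_b_samples
        )

    def source_ref(self, sample_id: str):
        for s, _, f in self.samples:
            if s == sample_id:
                return f
        raise InvalidInputError(f"unknown sample {sample_id!r}")

    @classmethod
    def from_csv(cls, path, contrast=None) -> "ExperimentDesign":
        """Load a design table with columns sample_id,condition,file,null_group.

        Null pairs are all sample pairs sharing a non-empty ``null_group``
        value.  If ``contrast`` is not given and the table holds exactly
        two conditions, they form the contrast in order of appearance.
        """
        df = pd.read_csv(path, dtype=str).fillna("")
        required = {"sample_id", "condition", "file", "null_group"}
        if not required.issubset(df.columns):
            raise InvalidInputError(
                f"design table needs columns {sorted(required)}, got {list(df.columns)}"
            )
        samples = [
            (row.sample_id, row.condition, row.file or None)
            for row in df.itertuples()
        ]
        null_pairs = []
        for group, sub in df[df["null_group"] != ""].groupby("null_group", sort=False):
            ids = list(sub["sample_id"])
            null_pairs.extend(
                (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
            )
        if contrast is None:
            conditions = list(dict.fromkeys(df["condition"]))
            if len(conditions) != 2:
                raise InvalidInputError(
                    "contrast must be given explicitly unless the design has "
                    f"exactly two conditions (found {conditions})"
                )
            contrast = (conditions[0], conditions[1])
        return cls(samples, contrast, null_pairs)

    def to_csv(self, path) -> None:
        rows = []
        group_of: dict[str, str] = {}
        for gi, (a, b) in enumerate(self.null_pairs):
            g = group_of.get(a) or group_of.get(b) or f"ng{gi}"
            group_of.setdefault(a, g)
            group_of.setdefault(b, g)
        for s, c, f in self.samples:
            rows.append(
                {"sample_id": s, "condition": c, "file": f or "",
                 "null_group": group_of.get(s, "")}
            )
        pd.DataFrame(rows).to_csv(path, index=False)
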