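"""Reading, aggregating, scaling and aligning multi-dataset rating panels.

The statistics in this package consume aligned per-dataset stimulus x
concept matrices of averaged intensity ratings.  Raw data arrive as
long-format tables of single ratings (one row per stimulus, dataset,
rater, concept) on a 0-100 intensity scale.  This module turns those
tables into :class:`RatingsPanel` objects: per-dataset averages, min-max
scaled to [0, 1] separately for every concept within every dataset.

Concept labels differ across datasets (translations of the same concept
lexicon); a :class:`ConceptLexicon` maps each dataset's display labels
back onto a shared ordered set of canonical concept keys so that column
``c`` means the same concept in every matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConceptLexicon",
    "RatingRecord",
    "RatingsPanel",
    "read_long_table",
    "average_panel",
    "scale_unit_interval",
    "align_panels",
    "read_wide",
    "write_panel",
]


def _normalize_label(label: str) -> str:
    """Canonical form used when matching concept labels: trim + case-fold."""
    return label.strip().casefold()


@dataclass(frozen=True)
class ConceptLexicon:
    """Ordered canonical concept keys plus per-dataset display labels.

    Parameters
    ----------
    keys
        Ordered tuple of P unique canonical concept keys.  These define
        the column order of every matrix built from this lexicon.
    translations
        Mapping ``dataset -> {key -> display label}``.  Datasets absent
        from the mapping fall back to the canonical keys themselves.
    """

    keys: tuple[str, ...]
    translations: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("concept keys must be unique")
        for dataset, table in self.translations.items():
            missing = set(self.keys) - set(table)
            if missing:
                raise ValueError(
                    f"translation table for {dataset!r} misses keys: {sorted(missing)}"
                )

    @classmethod
    def identity(cls, keys) -> "ConceptLexicon":
        """Lexicon whose display labels equal the canonical keys everywhere."""
        return cls(keys=tuple(keys))

    def _reverse(self, dataset: str) -> dict[str, str]:
        table = self.translations.get(dataset)
        rev = {_normalize_label(k): k for k in self.keys}
        if table is not None:
            rev.update({_normalize_label(v): k for k, v in table.items()})
        return rev

    def resolve(self, label: str, dataset: str) -> str:
        """Map a display label (any dataset) to its canonical key.

        Matching trims whitespace and case-folds; unknown labels raise
        ``KeyError``.
        """
        rev = self._reverse(dataset)
        norm = _normalize_label(label)
        if norm not in rev:
            raise KeyError(f"unknown concept label {label!r} for dataset {dataset!r}")
        return rev[norm]

    def to_tsv(self, path) -> None:
        datasets = sorted(self.translations)
        rows = []
        for key in self.keys:
            row = {"key": key}
            for d in datasets:
                row[d] = self.translations[d].get(key, key)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ConceptLexicon":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "key" not in df.columns:
            raise ValueError("lexicon file needs a 'key' column")
        keys = tuple(df["key"])
        translations = {
            d: dict(zip(keys, df[d])) for d in df.columns if d != "key"
        }
        return cls(keys=keys, translations=translations)


@dataclass(frozen=True)
class RatingRecord:
    """A single intensity rating of one concept for one stimulus."""

    stimulus_id: str
    dataset: str
    rater_id: str
    concept: str  # canonical key
    intensity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 100.0:
            raise ValueError(
                f"intensity {self.intensity} outside [0, 100] "
                f"(stimulus {self.stimulus_id}, rater {self.rater_id})"
            )


@dataclass
class RatingsPanel:
    """Aligned per-dataset stimulus x concept matrices.

    ``values[d]`` is an (N, P) array whose rows follow ``stimuli`` and
    whose columns follow ``concepts`` — identical ordering for every
    dataset, with no missing cells.  ``scaled`` records whether each
    concept column has been min-max scaled to [0, 1] within its dataset;
    ``constant_columns[d]`` flags columns that were constant before
    scaling (mapped to all zeros).
    """

    stimuli: list[str]
    datasets: list[str]
    concepts: list[str]
    values: dict[str, np.ndarray]
    scaled: bool = False
    constant_columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, p = len(self.stimuli), len(self.concepts)
        if len(set(self.stimuli)) != n:
            raise ValueError("duplicate stimulus ids")
        for d in self.datasets:
            if d not in self.values:
                raise ValueError(f"missing matrix for dataset {d!r}")
            mat = np.asarray(self.values[d], dtype=float)
            if mat.shape != (n, p):
                raise ValueError(
                    f"matrix for {d!r} has shape {mat.shape}, expected {(n, p)}"
                )
            self.values[d] = mat

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    def matrix(self, dataset: str) -> np.ndarray:
        return self.values[dataset]

    def subset(self, row_idx) -> "RatingsPanel":
        """Panel restricted to the given stimulus row indices (kept order)."""
        row_idx = np.asarray(row_idx)
        return RatingsPanel(
            stimuli=[self.stimuli[i] for i in row_idx],
            datasets=list(self.datasets),
            concepts=list(self.concepts),
            values={d: self.values[d][row_idx] for d in self.datasets},
            scaled=self.scaled,
            constant_columns=dict(self.constant_columns),
        )


def read_long_table(path, lexicon: ConceptLexicon) -> list[RatingRecord]:
    """Read a long-format rating table and validate it against a lexicon.

    The file must be CSV or TSV (separator inferred from the extension,
    ``.tsv``/``.txt`` meaning tab) with header columns ``stimulus_id,
    dataset, rater_id, concept, intensity``.  Concept labels are matched
    after trimming and case-folding; unknown labels and intensities
    outside [0, 100] are rejected with the offending row number.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"stimulus_id": str, "rater_id": str})
    required = ["stimulus_id", "dataset", "rater_id", "concept", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        intensity = float(row.intensity)
        if not 0.0 <= intensity <= 100.0:
            raise ValueError(
                f"row {pos}: intensity {intensity} outside [0, 100]"
            )
        try:
            key = lexicon.resolve(str(row.concept), str(row.dataset))
        except KeyError as exc:
            raise ValueError(f"row {pos}: {exc.args[0]}") from exc
        records.append(
            RatingRecord(
                stimulus_id=str(row.stimulus_id),
                dataset=str(row.dataset),
                rater_id=str(row.rater_id),
                concept=key,
                intensity=intensity,
            )
        )
    logger.info("read %d rating records from %s", len(records), path)
    return records


def average_panel(
    records,
    lexicon: ConceptLexicon,
    stimuli=None,
    unrated_as_zero: bool = True,
) -> RatingsPanel:
    """Average rating records into an unscaled :class:`RatingsPanel`.

    Cell (dataset a, stimulus i, concept c) is the mean over contributing
    ratings.  With ``unrated_as_zero`` (the default, matching a
    select-then-rate task where unselected concepts carry zero reported
    intensity) every rater who rated stimulus i in dataset a contributes
    an implicit 0 for each concept they did not select, so the
    denominator is the number of raters of that (dataset, stimulus).
    With ``unrated_as_zero=False`` the mean runs over explicit records
    only, and concept cells nobody rated are filled with 0 and logged.
    """
    records = list(records)
    if not records:
        raise ValueError("no rating records")
    concepts = list(lexicon.keys)
    cidx = {c: j for j, c in enumerate(concepts)}
    datasets = sorted({r.dataset for r in records})
    if stimuli is None:
        stimuli = sorted({r.stimulus_id for r in records})
    else:
        stimuli = list(stimuli)
    sidx = {s: i for i, s in enumerate(stimuli)}

    n, p = len(stimuli), len(concepts)
    sums = {d: np.zeros((n, p)) for d in datasets}
    counts = {d: np.zeros((n, p)) for d in datasets}
    raters: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.stimulus_id not in sidx:
            continue
        i, j = sidx[r.stimulus_id], cidx[r.concept]
        sums[r.dataset][i, j] += r.intensity
        counts[r.dataset][i, j] += 1
        raters.setdefault((r.dataset, r.stimulus_id), set()).add(r.rater_id)

    values = {}
    for d in datasets:
        n_raters = np.array(
            [len(raters.get((d, s), ())) for s in stimuli], dtype=float
        )
        empty = np.nonzero(n_raters == 0)[0]
        if empty.size and not unrated_as_zero:
            groups = [(d, stimuli[i]) for i in empty]
            raise ValueError(f"no ratings for (dataset, stimulus) groups: {groups}")
        if unrated_as_zero:
            denom = np.where(n_raters == 0, np.nan, n_raters)[:, None]
            mat = sums[d] / denom
            mat = np.nan_to_num(mat, nan=0.0)
            if empty.size:
                logger.warning(
                    "%d empty (dataset, stimulus) groups in %r filled with 0",
                    empty.size, d,
                )
        else:
            with np.errstate(invalid="ignore"):
                mat = sums[d] / counts[d]
            unfilled = ~np.isfinite(mat)
            if unfilled.any():
                logger.info(
                    "%d unrated cells in %r filled with 0", int(unfilled.sum()), d
                )
                mat[unfilled] = 0.0
        values[d] = mat
    return RatingsPanel(
        stimuli=stimuli, datasets=datasets, concepts=concepts, values=values
    )


def scale_unit_interval(panel: RatingsPanel) -> RatingsPanel:
    """Min-max scale every concept column to [0, 1] within each dataset.

    Scaling is per (dataset, concept): column x -> (x - min) / (max - min),
    so the same concept may be scaled by different ranges in different
    datasets.  Constant columns map to all zeros and are flagged in
    ``constant_columns`` rather than dropped, keeping concept indices
    aligned across datasets.  Idempotent on already-scaled panels.
    """
    values = {}
    flags = {}
    for d in panel.datasets:
        mat = panel.values[d]
        lo = mat.min(axis=0)
        hi = mat.max(axis=0)
        span = hi - lo
        constant = span <= 0
        safe = np.where(constant, 1.0, span)
        scaled = (mat - lo) / safe
        scaled[:, constant] = 0.0
        values[d] = scaled
        flags[d] = constant
        if constant.any():
            logger.info(
                "dataset %r: %d constant concept columns mapped to zero",
                d, int(constant.sum()),
            )
    return RatingsPanel(
        stimuli=list(panel.stimuli),
        datasets=list(panel.datasets),
        concepts=list(panel.concepts),
        values=values,
        scaled=True,
        constant_columns=flags,
    )


def align_panels(*panels: RatingsPanel) -> RatingsPanel:
    """Merge panels onto the intersection of their stimulus ids.

    All inputs must share the same concept order; dataset labels must be
    disjoint or identical matrices are rejected.  The merged panel keeps
    the first panel's relative stimulus order restricted to the shared
    ids; dropped ids are logged.  Fewer than 3 shared stimuli is an
    error (downstream covariances are undefined).  Idempotent.
    """
    if len(panels) < 1:
        raise ValueError("need at least one panel")
    concepts = list(panels[0].concepts)
    for p in panels[1:]:
        if list(p.concepts) != concepts:
            raise ValueError("panels disagree on concept order")
    shared = set(panels[0].stimuli)
    for p in panels[1:]:
        shared &= set(p.stimuli)
    order = [s for s in panels[0].stimuli if s in shared]
    if len(order) < 3:
        raise ValueError(
            f"only {len(order)} shared stimuli; need at least 3"
        )
    dropped = sum(len(p.stimuli) for p in panels) - len(order) * len(panels)
    if dropped:
        logger.info("align_panels dropped %d non-shared stimulus rows", dropped)

    datasets: list[str] = []
    values: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    scaled = all(p.scaled for p in panels)
    for p in panels:
        ridx = [p.stimuli.index(s) for s in order]
        for d in p.datasets:
            if d in values:
                raise ValueError(f"duplicate dataset label {d!r} across panels")
            datasets.append(d)
            values[d] = p.values[d][ridx]
            if d in p.constant_columns:
                flags[d] = p.constant_columns[d]
    if len(datasets) < 2:
        raise ValueError("aligned panel needs at least 2 datasets")
    return RatingsPanel(
        stimuli=order,
        datasets=datasets,
        concepts=concepts,
        values=values,
        scaled=scaled,
        constant_columns=flags,
    )


def read_wide(path, dataset: str, scaled: bool = False) -> RatingsPanel:
    """Read one dataset's wide matrix (stimulus rows, concept columns)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return RatingsPanel(
        stimuli=[str(s) for s in df.index],
        datasets=[dataset],
        concepts=[str(c) for c in df.columns],
        values={dataset: df.to_numpy(dtype=float)},
        scaled=scaled,
    )


def write_panel(panel: RatingsPanel, directory) -> None:
    """Write one wide-format TSV per dataset into ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for d in panel.datasets:
        df = pd.DataFrame(
            panel.values[d], index=panel.stimuli, columns=panel.concepts
        )
        df.index.name = "stimulus_id"
        df.to_csv(directory / f"{d}.tsv", sep="\t")
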