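"""Reading, validation, filtering and replicate aggregation of RT-qPCR Ct matrices.

A Ct (threshold-cycle) matrix holds one threshold-cycle value per sample and
miRNA.  Targets that never amplify within the instrument's cycle limit
(default 40 cycles) are right-censored: they are stored *at* the limit with an
explicit censoring flag rather than as missing values, which keeps every
downstream ΔCt computable while the flag preserves the information that the
value is a lower bound on abundance (upper bound on expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CYCLE_LIMIT = 40.0
DEFAULT_UNDETECTED_TOKEN = "Undetermined"

METADATA_COLUMNS = [
    "sample_id", "group", "split", "age", "sex", "smoker", "stage", "histology",
]

GROUPS = ("cancer", "control")
SPLITS = ("train", "test")


@dataclass
class CtMatrix:
    """Samples × miRNAs table of qPCR threshold-cycle values with censoring flags.

    Parameters
    ----------
    ct : pandas.DataFrame
        Ct values in cycles, index = sample ids, columns = miRNA ids.
    censored : pandas.DataFrame
        Boolean mask of the same shape; True where the target was undetected
        within ``cycle_limit`` cycles.  Censored cells store ``cycle_limit``
        in ``ct`` exactly.
    cycle_limit : float
        The instrument cycle cap, in cycles.
    """

    ct: pd.DataFrame
    censored: pd.DataFrame
    cycle_limit: float = DEFAULT_CYCLE_LIMIT

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        self.censored = self.censored.astype(bool)
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_samples(self) -> int:
        return self.ct.shape[0]

    @property
    def n_mirnas(self) -> int:
        return self.ct.shape[1]

    def validate(self) -> None:
        if self.ct.shape != self.censored.shape:
            raise ValueError(
                f"ct {self.ct.shape} and censored {self.censored.shape} shapes differ"
            )
        if not (self.ct.index.equals(self.censored.index)
                and self.ct.columns.equals(self.censored.columns)):
            raise ValueError("ct and censored must share index and columns")
        if self.ct.index.has_duplicates:
            dups = self.ct.index[self.ct.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.ct.columns.has_duplicates:
            dups = self.ct.columns[self.ct.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dups}")
        ctv = self.ct.to_numpy()
        cen = self.censored.to_numpy()
        if np.isnan(ctv).any():
            raise ValueError("Ct matrix contains NaN; use the censoring flag instead")
        if cen.any() and not np.all(ctv[cen] == self.cycle_limit):
            raise ValueError("censored cells must store ct == cycle_limit exactly")
        detected = ctv[~cen]
        if detected.size and (np.any(detected <= 0) or np.any(detected > self.cycle_limit)):
            raise ValueError(
                f"detected Ct values must lie in (0, {self.cycle_limit}]"
            )

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.ct.copy(), self.censored.copy(), self.cycle_limit)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CtMatrix":
        return CtMatrix(
            self.ct.loc[list(sample_ids)], self.censored.loc[list(sample_ids)],
            self.cycle_limit,
        )

    def equals(self, other: "CtMatrix", atol: float = 1e-9) -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.mirna_ids == other.mirna_ids
            and self.cycle_limit == other.cycle_limit
            and bool(np.allclose(self.ct.to_numpy(), other.ct.to_numpy(), atol=atol))
            and bool((self.censored.to_numpy() == other.censored.to_numpy()).all())
        )


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_ct_table(
    path: str | Path,
    cycle_limit: float = DEFAULT_CYCLE_LIMIT,
    undetected_token: str = DEFAULT_UNDETECTED_TOKEN,
    transposed: bool = False,
) -> CtMatrix:
    """Read a delimited Ct table into a :class:`CtMatrix`.

    The first column holds sample ids and the remaining columns are miRNAs
    (``transposed=True`` for miRNAs-in-rows exports).  Cells equal to
    ``undetected_token`` (case-insensitive) or empty are censored at
    ``cycle_limit``; numeric cells above the limit are clamped and flagged.
    """
    path = Path(path)
    sep = _sep_for(path)
    # pandas silently renames duplicate headers, so check the raw header line
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        kind = "sample ids" if transposed else "miRNA names"
        raise ValueError(f"{path}: duplicate {kind} {dups}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    if transposed:
        raw = raw.T
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        kind = "miRNA names" if transposed else "sample ids"
        raise ValueError(f"{path}: duplicate {kind} {dups}")

    token = undetected_token.strip().lower()
    ct = np.empty(raw.shape, dtype=float)
    cen = np.zeros(raw.shape, dtype=bool)
    n_clamped = 0
    for i, sid in enumerate(raw.index):
        for j, mid in enumerate(raw.columns):
            cell = str(raw.iat[i, j]).strip()
            if cell == "" or cell.lower() == token:
                ct[i, j] = cycle_limit
                cen[i, j] = True
                continue
            try:
                val = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at sample {sid!r}, "
                    f"miRNA {mid!r}"
                ) from exc
            if val > cycle_limit:
                ct[i, j] = cycle_limit
                cen[i, j] = True
                n_clamped += 1
            else:
                ct[i, j] = val
    if n_clamped:
        logger.info("%s: clamped %d Ct values above the %g-cycle limit",
                    path, n_clamped, cycle_limit)
    return CtMatrix(
        pd.DataFrame(ct, index=raw.index.astype(str), columns=raw.columns.astype(str)),
        pd.DataFrame(cen, index=raw.index.astype(str), columns=raw.columns.astype(str)),
        cycle_limit,
    )


def write_ct_table(
    m: CtMatrix,
    path: str | Path,
    undetected_token: str = DEFAULT_UNDETECTED_TOKEN,
    float_format: str = "%.6f",
) -> None:
    """Write a CtMatrix as delimited text; censored cells become the token."""
    path = Path(path)
    out = m.ct.map(lambda v: float_format % v)
    out = out.where(~m.censored, undetected_token)
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep_for(path))


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cohort metadata CSV and validate group/split labels."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = {"sample_id", "group", "split"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate metadata sample ids: {dups}")
    for col, allowed in (("group", GROUPS), ("split", SPLITS)):
        if meta[col].isna().any():
            raise ValueError(f"metadata column {col!r} has missing values")
        bad = set(meta[col].unique()) - set(allowed)
        if bad:
            raise ValueError(f"metadata column {col!r} has values {sorted(bad)}; "
                             f"allowed: {allowed}")
    return meta


def check_metadata_covers(m: CtMatrix, meta: pd.DataFrame) -> None:
    """Every sample in the Ct matrix must have exactly one metadata row."""
    missing = set(m.sample_ids) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}...")


def filter_globally_undetected(m: CtMatrix) -> CtMatrix:
    """Drop miRNAs undetected (censored) in every sample.

    Mirrors the screening pre-filter that reduces the assayed panel to the
    targets that amplified within the cycle limit in at least one sample.
    Column order of the retained miRNAs is preserved.
    """
    detected_any = ~m.censored.to_numpy().all(axis=0)
    if not detected_any.any():
        raise ValueError("all miRNAs are undetected in every sample")
    keep = m.ct.columns[detected_any]
    n_dropped = m.n_mirnas - len(keep)
    if n_dropped:
        logger.info("dropped %d globally undetected miRNAs, %d retained",
                    n_dropped, len(keep))
    return CtMatrix(m.ct.loc[:, keep], m.censored.loc[:, keep], m.cycle_limit)


def aggregate_replicates(matrices: Sequence[CtMatrix]) -> CtMatrix:
    """Combine replicate RT/qPCR runs into one Ct matrix.

    Per cell, the mean of the *detected* replicate Ct values; a cell is
    censored only when every replicate was censored (it then stores the
    cycle limit).
    """
    if len(matrices) == 0:
        raise ValueError("need at least one replicate matrix")
    first = matrices[0]
    for k, m in enumerate(matrices[1:], start=2):
        if (m.sample_ids != first.sample_ids or m.mirna_ids != first.mirna_ids
                or m.cycle_limit != first.cycle_limit):
            raise ValueError(f"replicate {k} has mismatched samples/miRNAs/limit")
    ct = np.stack([m.ct.to_numpy() for m in matrices])        # (k, n, m)
    cen = np.stack([m.censored.to_numpy() for m in matrices])
    detected = ~cen
    n_det = detected.sum(axis=0)
    all_censored = n_det == 0
    summed = np.where(detected, ct, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_ct = np.where(all_censored, first.cycle_limit,
                           summed / np.maximum(n_det, 1))
    return CtMatrix(
        pd.DataFrame(mean_ct, index=first.ct.index, columns=first.ct.columns),
        pd.DataFrame(all_censored, index=first.ct.index, columns=first.ct.columns),
        first.cycle_limit,
    )
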