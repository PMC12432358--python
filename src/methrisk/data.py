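"""Data model and I/O for methylation matrices and phenotype tables.

Methylation is carried as beta-values (the fraction of methylated alleles
at a CpG site, in [0, 1]) and converted to M-values (logit2 of beta) on
demand for model fitting; group means and delta-beta are reported on the
beta scale, which is what clinicians read.

File dialect is deliberately rigid: comma-delimited, decimal point,
mandatory header. One bit-exact dialect beats autodetection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

M_EPS = 1e-6

__all__ = [
    "MethylationMatrix",
    "PhenotypeTable",
    "ProbeMask",
    "FormatError",
    "beta_to_m",
    "m_to_beta",
    "intensity_to_m",
    "filter_probes",
    "read_matrix",
    "write_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_probe_mask",
]


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected dialect or invariants."""


def beta_to_m(beta):
    """Convert beta-values to M-values: M = log2(beta / (1 - beta)).

    Exact 0/1 are clipped to [eps, 1 - eps] (eps = 1e-6) so the transform
    stays finite; elsewhere the mapping is a bijection.
    """
    beta = np.clip(np.asarray(beta, dtype=float), M_EPS, 1.0 - M_EPS)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (2^M + 1)."""
    m = np.asarray(m, dtype=float)
    # expit in base 2, computed stably for large |M|
    out = np.where(m >= 0, 1.0 / (1.0 + np.exp2(-m)), np.exp2(m) / (1.0 + np.exp2(m)))
    return out


def intensity_to_m(meth_intensity, unmeth_intensity):
    """M-value from raw array channel intensities.

    M = log2((max(meth, 0) + 1) / (max(unmeth, 0) + 1)); negative
    intensities (background over-correction) are clamped to zero before the
    +1 offset.
    """
    meth = np.asarray(meth_intensity, dtype=float)
    unmeth = np.asarray(unmeth_intensity, dtype=float)
    if not (np.all(np.isfinite(meth)) and np.all(np.isfinite(unmeth))):
        raise ValueError("channel intensities must be finite")
    return np.log2((np.maximum(meth, 0.0) + 1.0) / (np.maximum(unmeth, 0.0) + 1.0))


@dataclass
class MethylationMatrix:
    """A sites x samples methylation matrix.

    Attributes
    ----------
    site_ids : list of probe IDs (rows), unique, order preserved.
    sample_ids : list of sample IDs (columns), unique, order preserved.
    values : float array, shape (n_sites, n_samples).
    scale : "beta" (values in [0, 1]) or "m" (logit2 scale).
    """

    site_ids: list
    sample_ids: list
    values: np.ndarray
    scale: Literal["beta", "m"] = "beta"

    def __post_init__(self):
        self.site_ids = list(self.site_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.sample_ids)} samples"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise FormatError("duplicate site IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample IDs")
        if np.isnan(self.values).any():
            raise FormatError("missing values are not permitted after loading")
        if self.scale == "beta" and ((self.values < 0) | (self.values > 1)).any():
            i, j = np.argwhere((self.values < 0) | (self.values > 1))[0]
            raise FormatError(
                f"beta value out of [0, 1] at site {self.site_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_m(self) -> "MethylationMatrix":
        """Return an M-scale view of the matrix (identity if already M)."""
        if self.scale == "m":
            return self
        return MethylationMatrix(self.site_ids, self.sample_ids, beta_to_m(self.values), "m")

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == "beta":
            return self
        return MethylationMatrix(self.site_ids, self.sample_ids, m_to_beta(self.values), "beta")

    def site(self, site_id) -> np.ndarray:
        """Values for one site, ordered as sample_ids."""
        return self.values[self.site_ids.index(site_id)]

    def subset_sites(self, keep: Sequence) -> "MethylationMatrix":
        keep = list(keep)
        idx = {s: i for i, s in enumerate(self.site_ids)}
        rows = [idx[s] for s in keep]
        return MethylationMatrix(keep, self.sample_ids, self.values[rows], self.scale)

    def subset_samples(self, keep: Sequence) -> "MethylationMatrix":
        keep = list(keep)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in keep]
        return MethylationMatrix(self.site_ids, keep, self.values[:, cols], self.scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.site_ids, name="probe_id"),
                            columns=self.sample_ids)


# Mandatory phenotype columns and their checks. Optional lipid/renal columns
# (hdl, ldl, tg, egfr, uacr) pass through untouched when present.
PHENOTYPE_REQUIRED = [
    "sample_id", "event", "time_years", "age", "gender", "bmi", "hba1c",
    "smoking_proxy", "med_diabetes", "med_lipid", "med_antihypertensive",
]
PHENOTYPE_OPTIONAL = ["hdl", "ldl", "tg", "egfr", "uacr"]


@dataclass
class PhenotypeTable:
    """Per-sample outcome and covariates.

    `event` is 1 for an incident macrovascular event during follow-up and 0
    for a censored control; `time_years` is the observed follow-up time.
    `smoking_proxy` is the beta-value of cg05575921 (AHRR), the standard
    blood methylation biomarker of smoking.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing = [c for c in PHENOTYPE_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample IDs in phenotype table")
        if not df["event"].isin([0, 1]).all():
            raise FormatError("event must be 0/1")
        if (df["time_years"] <= 0).any():
            raise FormatError("time_years must be positive")
        if ((df["smoking_proxy"] < 0) | (df["smoking_proxy"] > 1)).any():
            raise FormatError("smoking_proxy must be a beta-value in [0, 1]")
        if not df["gender"].isin(["male", "female"]).all():
            raise FormatError("gender must be 'male' or 'female'")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return self.table["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def time_years(self) -> np.ndarray:
        return self.table["time_years"].to_numpy(dtype=float)

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Numeric design columns for the requested covariates.

        `gender` is encoded as male=1/female=0; all other columns are taken
        as numeric as-is.
        """
        cols = []
        for name in names:
            if name == "gender":
                cols.append((self.table["gender"] == "male").to_numpy(dtype=float))
            else:
                if name not in self.table.columns:
                    raise KeyError(f"covariate {name!r} not in phenotype table")
                cols.append(self.table[name].to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((self.n_samples, 0))

    def subset(self, sample_ids: Sequence) -> "PhenotypeTable":
        df = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return PhenotypeTable(df)


@dataclass
class ProbeMask:
    """A named set of probe IDs to exclude (detection-p failures,
    cross-reactive probes, polymorphic probes, ...)."""

    name: str
    probe_ids: set = field(default_factory=set)

    def __post_init__(self):
        self.probe_ids = set(self.probe_ids)
        if not self.probe_ids:
            raise ValueError(f"probe mask {self.name!r} is empty")


def filter_probes(matrix: MethylationMatrix, masks: Iterable[ProbeMask]) -> MethylationMatrix:
    """Drop the union of masked probes from a matrix, preserving site order.

    Mask IDs absent from the matrix are ignored (a count is logged per
    mask). Raises ValueError if every probe would be removed.
    """
    masks = list(masks)
    present = set(matrix.site_ids)
    removed = set()
    for mask in masks:
        hit = mask.probe_ids & present
        unmatched = len(mask.probe_ids) - len(hit)
        logger.info("probe mask %s: %d probes removed, %d unmatched", mask.name, len(hit), unmatched)
        removed |= hit
    keep = [s for s in matrix.site_ids if s not in removed]
    if not keep:
        raise ValueError("all probes removed by masks")
    if len(keep) == matrix.n_sites:
        return matrix
    return matrix.subset_sites(keep)


def read_matrix(path, scale: Literal["beta", "m"] = "beta") -> MethylationMatrix:
    """Read a methylation matrix CSV: first column probe_id, one column per sample."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise FormatError(f"non-numeric cells in columns {list(bad)} of {path}")
    return MethylationMatrix(df.index.tolist(), df.columns.tolist(), vals, scale)


def write_matrix(matrix: MethylationMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # repr float formatting keeps the round trip exact to >=10 significant digits
    matrix.to_frame().to_csv(path, float_format="%.17g")


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


def write_phenotypes(phenotypes: PhenotypeTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    phenotypes.table.to_csv(path, index=False, float_format="%.17g")


def read_probe_mask(path, name: str | None = None) -> ProbeMask:
    """Read a one-probe-ID-per-line mask file."""
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return ProbeMask(name or Path(path).stem, set(ids))
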