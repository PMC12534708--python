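"""Domain types, file readers/writers, replicate-probe handling, probe QC.

Beta matrices are probes x samples tables of methylation fractions in [0, 1]
with NA support; they are the universal currency of every analysis stage.
Coordinates are 0-based half-open (BED convention) everywhere.
"""

from __future__ import annotations

import io as _stdio
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ProbeManifest",
    "SampleSheet",
    "GenomicIntervalSet",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_intervals",
    "write_intervals",
    "read_probe_set",
    "write_probe_set",
    "collapse_replicates",
    "replicate_sd_profile",
    "probe_sequence_qc",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "NAN"}


class BetaMatrixError(ValueError):
    """Malformed or out-of-range beta-value input."""


class BetaMatrix:
    """Probes x samples matrix of beta values in [0, 1], NaN for missing.

    Thin validated wrapper around a float ``pandas.DataFrame`` whose index
    holds probe IDs and whose columns hold sample IDs.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("BetaMatrix expects a pandas DataFrame")
        data = data.astype(float)
        if validate:
            if data.index.has_duplicates:
                dups = data.index[data.index.duplicated()].unique().tolist()
                raise BetaMatrixError(f"duplicate probe IDs: {dups[:5]}")
            if data.columns.has_duplicates:
                dups = data.columns[data.columns.duplicated()].unique().tolist()
                raise BetaMatrixError(f"duplicate sample IDs: {dups[:5]}")
            vals = data.to_numpy()
            bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                i, j = np.argwhere(bad & ~np.isnan(vals))[0]
                raise BetaMatrixError(
                    f"beta value {vals[i, j]!r} out of [0, 1] at probe "
                    f"{data.index[i]!r}, sample {data.columns[j]!r}"
                )
        self.data = data

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(probes)], validate=False)

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[:, list(samples)], validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_na = int(np.isnan(self.data.to_numpy()).sum())
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples, {n_na} NA)"


@dataclass
class ProbeManifest:
    """Per-probe genomic interval, replicate grouping, and optional sequence.

    ``table`` columns: probe_id, chrom, start, end (0-based half-open),
    optional replicate_prefix, sequence, cpg_count_extra,
    snp_offsets_from_3prime (comma-separated string of integers or NA).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"probe_id", "chrom", "start", "end"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if t["probe_id"].duplicated().any():
            raise ValueError("duplicate probe_id in manifest")
        if (t["start"].to_numpy() >= t["end"].to_numpy()).any():
            bad = t.loc[t["start"] >= t["end"], "probe_id"].iloc[0]
            raise ValueError(f"start >= end for probe {bad!r}")
        if "replicate_prefix" in t.columns:
            ok = [
                (isinstance(p, str) and isinstance(i, str) and i.startswith(p)) or pd.isna(p)
                for p, i in zip(t["replicate_prefix"], t["probe_id"])
            ]
            if not all(ok):
                bad = t.loc[[not o for o in ok], "probe_id"].iloc[0]
                raise ValueError(f"replicate_prefix is not a prefix of probe_id for {bad!r}")
        self.table = t.reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def replicate_groups(self) -> pd.Series:
        """probe_id -> replicate_prefix (probe_id itself if no prefix column)."""
        t = self.table
        if "replicate_prefix" in t.columns:
            pref = t["replicate_prefix"].where(t["replicate_prefix"].notna(), t["probe_id"])
        else:
            pref = t["probe_id"]
        return pd.Series(pref.to_numpy(), index=t["probe_id"].to_numpy(), name="replicate_prefix")

    def intervals(self, names: str = "probe_id") -> "GenomicIntervalSet":
        t = self.table
        return GenomicIntervalSet(
            pd.DataFrame(
                {"chrom": t["chrom"], "start": t["start"], "end": t["end"], "name": t[names]}
            )
        )


@dataclass
class SampleSheet:
    """Sample metadata: sample_id, tissue, optional age / sex / modality / donor."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"sample_id", "tissue"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        if "age" in t.columns:
            ages = pd.to_numeric(t["age"], errors="coerce")
            if (ages.dropna() < 0).any():
                raise ValueError("negative age in sample sheet")
            t = t.assign(age=ages)
        if "sex" in t.columns:
            bad = set(t["sex"].dropna()) - {"F", "M"}
            if bad:
                raise ValueError(f"sex labels must be F/M, got {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def groups(self, column: str = "tissue") -> pd.Series:
        return pd.Series(
            self.table[column].to_numpy(), index=self.table["sample_id"].to_numpy(), name=column
        )


@dataclass
class GenomicIntervalSet:
    """Records of (chrom, start, end, name), 0-based half-open."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"chrom", "start", "end"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"interval set missing columns: {sorted(missing)}")
        if "name" not in t.columns:
            t = t.assign(name=[f"iv{i}" for i in range(len(t))])
        t = t.astype({"start": np.int64, "end": np.int64})
        if (t["start"].to_numpy() > t["end"].to_numpy()).any():
            raise ValueError("interval with start > end")
        if (t["start"].to_numpy() < 0).any():
            raise ValueError("negative interval start")
        self.table = t.reset_index(drop=True)

    def sorted(self) -> "GenomicIntervalSet":
        return GenomicIntervalSet(
            self.table.sort_values(["chrom", "start", "end", "name"], kind="mergesort")
        )

    def expand(self, bp: int) -> "GenomicIntervalSet":
        """Expand every interval by ``bp`` on each side, clamping starts at 0."""
        t = self.table.copy()
        t["start"] = np.maximum(t["start"] - bp, 0)
        t["end"] = t["end"] + bp
        return GenomicIntervalSet(t)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path: str | Path, dialect: str = "tsv") -> BetaMatrix:
    """Read a probes x samples beta table (first column probe IDs, header samples).

    Empty cells, ``NA`` and ``NaN`` denote missing; any other non-numeric cell
    and any value outside [0, 1] raise ``BetaMatrixError`` with coordinates.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.columns.size == 0:
        raise BetaMatrixError(f"{path}: no sample columns in header")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].str.strip()
        is_na = raw.isin(_MISSING_TOKENS)
        vals = pd.to_numeric(raw.where(~is_na, np.nan), errors="coerce")
        bad = vals.isna() & ~is_na
        if bad.any():
            probe = df.index[bad.to_numpy()][0]
            raise BetaMatrixError(
                f"{path}: non-numeric cell {raw[bad].iloc[0]!r} at probe {probe!r}, sample {col!r}"
            )
        out.iloc[:, j] = vals.to_numpy()
    try:
        return BetaMatrix(out)
    except BetaMatrixError as err:
        raise BetaMatrixError(f"{path}: {err}") from None


def write_beta_matrix(bm: BetaMatrix, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = bm.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")


def read_manifest(path: str | Path, one_based: bool = False) -> ProbeManifest:
    """Read a BED4+ style manifest TSV with a header row.

    ``one_based=True`` converts inclusive 1-based starts to 0-based half-open
    at this boundary.
    """
    t = pd.read_csv(path, sep="\t")
    if one_based:
        t["start"] = t["start"] - 1
    return ProbeManifest(t)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False, na_rep="NA")


def read_intervals(path: str | Path) -> GenomicIntervalSet:
    """Read a BED3/BED4 file (no header)."""
    t = pd.read_csv(path, sep="\t", header=None, comment="#")
    t = t.iloc[:, :4] if t.shape[1] >= 4 else t.iloc[:, :3]
    t.columns = ["chrom", "start", "end", "name"][: t.shape[1]]
    return GenomicIntervalSet(t)


def write_intervals(ivs: GenomicIntervalSet, path: str | Path) -> None:
    ivs.sorted().table[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_probe_set(path: str | Path) -> list[str]:
    """One probe ID per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_probe_set(probes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p}\n")


# ---------------------------------------------------------------------------
# replicate probes


def collapse_replicates(
    bm: BetaMatrix, manifest: ProbeManifest, method: str = "mean"
) -> BetaMatrix:
    """Collapse replicate probe groups (shared ID prefix) to one row per prefix.

    Value = mean of non-NA replicate betas; all-NA groups stay NA. Idempotent
    on its own output. Probes absent from the manifest raise ``KeyError``.
    """
    if method != "mean":
        raise ValueError(f"unsupported collapse method {method!r}")
    groups = manifest.replicate_groups()
    missing = bm.probe_ids.difference(groups.index)
    if len(missing):
        raise KeyError(f"probes missing from manifest: {list(missing[:5])}")
    prefix = groups.loc[bm.probe_ids]
    collapsed = bm.data.groupby(prefix.to_numpy(), sort=False).mean()
    collapsed.index.name = bm.data.index.name
    return BetaMatrix(collapsed, validate=False)


def replicate_sd_profile(
    bm: BetaMatrix,
    manifest: ProbeManifest,
    n_nonreplicate_pairs: int = 1000,
    seed: int = 0,
) -> dict:
    """Within-sample SD of replicate probe groups vs. random non-replicate pairs.

    For each replicate group (>= 2 probes), the sample SD (n-1 denominator) of
    replicate betas is computed within every sample and averaged over samples.
    A contrast distribution is built from randomly paired non-replicate probes.

    Returns a dict with ``groups`` (DataFrame: prefix, n_probes, mean_sd),
    ``mean_sd`` (grand mean over groups) and ``nonreplicate_sds`` (array).
    """
    groups = manifest.replicate_groups().loc[bm.probe_ids]
    sizes = groups.value_counts()
    multi = sizes[sizes >= 2].index
    rows = []
    for prefix in multi:
        sub = bm.data.loc[groups[groups == prefix].index].to_numpy()
        with np.errstate(invalid="ignore"):
            per_sample_sd = _nanstd1(sub, axis=0)
        rows.append((prefix, sub.shape[0], float(np.nanmean(per_sample_sd))))
    table = pd.DataFrame(rows, columns=["prefix", "n_probes", "mean_sd"])
    if table.empty:
        import warnings

        warnings.warn("no replicate groups with >= 2 probes", stacklevel=2)
        return {"groups": table, "mean_sd": float("nan"), "nonreplicate_sds": np.array([])}
    rng = np.random.default_rng(seed)
    singles = np.asarray(groups.index)
    non_sds = []
    vals = bm.data.to_numpy()
    pos = {p: i for i, p in enumerate(bm.probe_ids)}
    for _ in range(n_nonreplicate_pairs):
        a, b = rng.choice(len(singles), size=2, replace=False)
        if groups.iloc[a] == groups.iloc[b]:
            continue
        pair = vals[[pos[singles[a]], pos[singles[b]]]]
        with np.errstate(invalid="ignore"):
            non_sds.append(float(np.nanmean(_nanstd1(pair, axis=0))))
    return {
        "groups": table,
        "mean_sd": float(table["mean_sd"].mean()),
        "nonreplicate_sds": np.asarray(non_sds),
    }


def _nanstd1(a: np.ndarray, axis: int) -> np.ndarray:
    """NaN-aware sample SD (n-1 denominator); NaN where fewer than 2 values."""
    n = np.sum(~np.isnan(a), axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(a, axis=axis, ddof=1)
    return np.where(n >= 2, sd, np.nan)


# ---------------------------------------------------------------------------
# probe sequence QC

_MAX_EXTRA_CPGS = 6  # designs with more additional CpGs interfere with hybridization
_SNP_3PRIME_WINDOW = 5  # SNPs within 5 nt of the 3' end compromise extension


def count_extra_cpgs(sequence: str) -> int:
    """CG dinucleotides in the probe sequence excluding the assayed CpG.

    Overlapping occurrences are counted by sliding window; the assayed site
    itself is not part of the probe body in Infinium designs, so every CG in
    the sequence counts as "additional". Case-insensitive.
    """
    s = sequence.upper()
    return sum(1 for i in range(len(s) - 1) if s[i : i + 2] == "CG")


def probe_sequence_qc(manifest: ProbeManifest) -> pd.DataFrame:
    """Probe designability QC on sequence composition and SNP proximity.

    Fails a probe with reason ``excess_cpg`` when additional CpGs > 6 and with
    reason ``snp_3prime`` when any SNP lies within 5 nt of the 3' end
    (offset 1 = terminal base); both reasons may co-occur. Decisions depend
    only on sequence/offset annotations, never on beta values.
    """
    t = manifest.table
    have_seq = "sequence" in t.columns
    have_counts = "cpg_count_extra" in t.columns
    have_snp = "snp_offsets_from_3prime" in t.columns
    if not (have_seq or have_counts or have_snp):
        raise KeyError(
            "manifest provides neither 'sequence' nor precomputed "
            "'cpg_count_extra'/'snp_offsets_from_3prime' columns"
        )
    records = []
    for _, row in t.iterrows():
        reasons: list[str] = []
        n_extra = None
        if have_counts and pd.notna(row.get("cpg_count_extra")):
            n_extra = int(row["cpg_count_extra"])
        elif have_seq and isinstance(row.get("sequence"), str):
            n_extra = count_extra_cpgs(row["sequence"])
        if n_extra is not None and n_extra > _MAX_EXTRA_CPGS:
            reasons.append("excess_cpg")
        if have_snp and pd.notna(row.get("snp_offsets_from_3prime")):
            raw = str(row["snp_offsets_from_3prime"])
            offsets = [int(x) for x in re.split(r"[,;]", raw) if x.strip()]
            if any(1 <= off <= _SNP_3PRIME_WINDOW for off in offsets):
                reasons.append("snp_3prime")
        records.append((row["probe_id"], not reasons, reasons))
    return pd.DataFrame(records, columns=["probe_id", "pass", "reasons"])
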