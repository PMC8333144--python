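"""Genotype/phenotype tables, daily aggregation, and marker binning.

Phenotypes live in long format (individual, trait, stage, day, value) on a
shared stage-labelled daily grid; genotypes are biallelic homozygous codes
(0 = qq, 2 = QQ) from an introgression-line design, with map positions.
Cosegregating adjacent markers are collapsed into chromosome bins before
scanning.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("individual_id", "trait_id", "stage_id", "day", "value")
GENOTYPE_META_COLUMNS = ("marker_id", "chromosome", "position_cM")

#: accepted homozygous genotype dialects, normalised to {0.0, 2.0}
_CODE_MAP = {
    "0": 0.0, "2": 2.0, "0.0": 0.0, "2.0": 2.0,
    "qq": 0.0, "QQ": 2.0, "A": 0.0, "B": 2.0, "a": 0.0, "b": 2.0,
}
_HET_CODES = {"1", "1.0", "Qq", "qQ", "Aa", "aA", "AB", "BA"}
_MISSING_CODES = {"", "na", "nan", "NA", "NaN", ".", "-", "missing", "None"}


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class AlignmentError(ValueError):
    """Observations do not share the common (stage, day) grid."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class PhenotypeSeries:
    """Long-format longitudinal phenotypes on a stage-labelled daily grid."""

    data: pd.DataFrame
    stage_order: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"phenotype table missing columns: {missing}")
        if not self.stage_order:
            self.stage_order = list(pd.unique(self.data["stage_id"]))
        df = self.data.copy()
        df["_stage_rank"] = df["stage_id"].map(
            {s: i for i, s in enumerate(self.stage_order)}
        )
        df = df.sort_values(["individual_id", "trait_id", "_stage_rank", "day"])
        self.data = df.drop(columns="_stage_rank").reset_index(drop=True)

    @property
    def individuals(self) -> list:
        return sorted(self.data["individual_id"].unique().tolist())

    @property
    def traits(self) -> list:
        return sorted(self.data["trait_id"].unique().tolist())

    @property
    def stages(self) -> list:
        return list(self.stage_order)

    def grid(self) -> dict:
        """Mapping stage_id -> sorted array of days present for that stage."""
        return {
            s: np.sort(self.data.loc[self.data["stage_id"] == s, "day"].unique())
            for s in self.stage_order
        }

    def stage_lengths(self) -> list:
        g = self.grid()
        return [len(g[s]) for s in self.stage_order]

    def n_timepoints(self) -> int:
        return int(sum(self.stage_lengths()))

    def to_matrix(self, trait_id=None):
        """Wide (n_individuals, M) matrix over the concatenated grid.

        Columns are ordered stage-by-stage (and trait-by-trait when
        ``trait_id`` is None and several traits are present, trait-major).
        Raises :class:`AlignmentError` if any individual misses a grid cell.
        """
        traits = [trait_id] if trait_id is not None else self.traits
        grid = self.grid()
        inds = self.individuals
        blocks = []
        for tr in traits:
            sub = self.data[self.data["trait_id"] == tr]
            piv = sub.pivot_table(
                index="individual_id", columns=["stage_id", "day"], values="value"
            )
            cols = [(s, d) for s in self.stage_order for d in grid[s]]
            try:
                piv = piv.reindex(index=inds, columns=cols)
            except KeyError as exc:  # pragma: no cover - defensive
                raise AlignmentError(str(exc)) from exc
            if piv.isna().any().any():
                bad = piv.index[piv.isna().any(axis=1)].tolist()[:5]
                raise AlignmentError(
                    f"individuals {bad} do not cover the full (stage, day) grid "
                    f"for trait {tr!r}"
                )
            blocks.append(piv.to_numpy(dtype=float))
        return inds, np.hstack(blocks)


@dataclass
class GenotypeTable:
    """Marker x individual genotype codes with map positions.

    ``codes`` is (n_markers, n_individuals) float with values in {0, 2} and
    NaN for missing; markers are sorted by (chromosome, position_cM).
    """

    markers: pd.DataFrame  # columns marker_id, chromosome, position_cM
    individuals: list
    codes: np.ndarray

    def __post_init__(self):
        missing = [c for c in GENOTYPE_META_COLUMNS if c not in self.markers.columns]
        if missing:
            raise SchemaError(f"genotype table missing columns: {missing}")
        order = np.lexsort(
            (self.markers["position_cM"].to_numpy(),
             self.markers["chromosome"].astype(str).to_numpy())
        )
        self.markers = self.markers.iloc[order].reset_index(drop=True)
        self.codes = np.asarray(self.codes, dtype=float)[order]
        bad = ~(np.isnan(self.codes) | (self.codes == 0.0) | (self.codes == 2.0))
        if bad.any():
            raise ValueError(
                "genotype codes must be in {0, 2} or missing after normalisation"
            )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def subset_individuals(self, ids) -> "GenotypeTable":
        pos = [self.individuals.index(i) for i in ids]
        return GenotypeTable(
            self.markers.copy(), list(ids), self.codes[:, pos].copy()
        )


@dataclass
class BinnedMarkers:
    """Cosegregation bins: runs of adjacent identical genotype columns."""

    bins: pd.DataFrame  # bin_id, chromosome, cM_min, cM_max, n_markers, member_marker_ids
    individuals: list
    codes: np.ndarray  # representative genotype column per bin

    @property
    def n_bins(self) -> int:
        return len(self.bins)


# ---------------------------------------------------------------------------
# readers


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_phenotype_table(path, schema: dict | None = None) -> PhenotypeSeries:
    """Read a long-format phenotype CSV.

    ``schema`` optionally maps the canonical column names
    (individual_id, trait_id, stage_id, day, value) to the file's column
    names.  Rows with missing or unparseable values are dropped and the
    count is logged.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh)
    schema = schema or {}
    rename = {schema.get(c, c): c for c in PHENOTYPE_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise SchemaError(f"phenotype file {path} missing column(s): {missing}")
    df = df.rename(columns=rename)[list(PHENOTYPE_COLUMNS)]
    n0 = len(df)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["day"] = pd.to_numeric(df["day"], errors="coerce")
    df = df.dropna(subset=["individual_id", "trait_id", "stage_id", "day", "value"])
    dropped = n0 - len(df)
    if dropped:
        logger.info("read_phenotype_table: dropped %d row(s) with missing values", dropped)
    stage_order = list(pd.unique(df["stage_id"]))
    return PhenotypeSeries(df.reset_index(drop=True), stage_order)


def normalize_genotype_codes(values) -> np.ndarray:
    """Normalise a genotype column to {0.0, 2.0, NaN}.

    Accepts the {0,2}, {qq,QQ} and {A,B} dialects.  Heterozygote codes are
    rejected: the introgression-line design has two homozygous classes only.
    """
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        if isinstance(v, float) and np.isnan(v):
            out[i] = np.nan
            continue
        s = str(v).strip()
        if s in _MISSING_CODES:
            out[i] = np.nan
        elif s in _HET_CODES:
            raise ValueError(
                f"heterozygous genotype code {s!r} is not valid for the "
                "two-genotype introgression-line design"
            )
        elif s in _CODE_MAP:
            out[i] = _CODE_MAP[s]
        else:
            raise ValueError(f"unrecognised genotype code {s!r}")
    return out


def read_genotype_table(path) -> GenotypeTable:
    """Read a genotype CSV: marker_id, chromosome, position_cM, then one
    column per individual."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh)
    missing = [c for c in GENOTYPE_META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"genotype file {path} missing column(s): {missing}")
    ind_cols = [c for c in df.columns if c not in GENOTYPE_META_COLUMNS]
    if not ind_cols:
        raise SchemaError(f"genotype file {path} has no individual columns")
    codes = np.column_stack([normalize_genotype_codes(df[c].tolist()) for c in ind_cols])
    meta = df[list(GENOTYPE_META_COLUMNS)].copy()
    meta["position_cM"] = pd.to_numeric(meta["position_cM"])
    return GenotypeTable(meta, ind_cols, codes)


def read_genotype_vcf(path) -> GenotypeTable:
    """Read biallelic homozygous genotypes from a VCF (0/0 -> 0, 1/1 -> 2).

    Heterozygous calls are rejected (introgression-line mode); positions are
    taken from the POS field and reported in the cM column as-is.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        gts = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if np.any(gts == 1):
            raise ValueError(
                f"heterozygous call at {var.CHROM}:{var.POS}; not valid in IL mode"
            )
        codes = np.where(gts == 0, 0.0, np.where(gts == 3, 2.0, np.nan))
        rows.append(codes)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, float(var.POS)))
    markers = pd.DataFrame(meta, columns=list(GENOTYPE_META_COLUMNS))
    return GenotypeTable(markers, individuals, np.asarray(rows))


# ---------------------------------------------------------------------------
# daily aggregation


def aggregate_daily(raw: pd.DataFrame, stage_boundaries) -> PhenotypeSeries:
    """Aggregate high-frequency measurements to one value per day.

    Parameters
    ----------
    raw : DataFrame with columns individual_id, trait_id (optional), day or
        timestamp (fractional days), value.  The daily value is the mean of
        that day's measurements.
    stage_boundaries : list of (stage_id, day_min, day_max), inclusive,
        ordered and non-overlapping; each day is assigned to its stage.
    """
    raw = raw.copy()
    if "trait_id" not in raw.columns:
        raw["trait_id"] = "trait"
    if "day" not in raw.columns:
        if "timestamp" not in raw.columns:
            raise SchemaError("raw series needs a 'day' or 'timestamp' column")
        raw["day"] = np.floor(pd.to_numeric(raw["timestamp"], errors="raise")).astype(int)
    else:
        raw["day"] = np.floor(pd.to_numeric(raw["day"], errors="raise")).astype(int)

    spans = sorted(stage_boundaries, key=lambda b: b[1])
    for (sa, a0, a1), (sb, b0, b1) in zip(spans, spans[1:]):
        if a1 >= b0:
            raise ValueError(
                f"overlapping stage ranges: {sa!r} ({a0}-{a1}) and {sb!r} ({b0}-{b1})"
            )

    def assign(day):
        for sid, lo, hi in spans:
            if lo <= day <= hi:
                return sid
        return None

    daily = (
        raw.groupby(["individual_id", "trait_id", "day"], as_index=False)["value"]
        .mean()
    )
    daily["stage_id"] = daily["day"].map(assign)
    daily = daily[daily["stage_id"].notna()]

    # every individual must cover every day inside the stage spans it touches
    all_days = np.sort(daily["day"].unique())
    gaps = []
    for ind, sub in daily.groupby("individual_id"):
        missing = set(all_days) - set(sub["day"])
        if missing:
            gaps.append((ind, sorted(missing)))
    if gaps:
        raise ValueError(f"days with zero measurements: {gaps}")

    stage_order = [s for s, _, _ in spans]
    return PhenotypeSeries(
        daily[["individual_id", "trait_id", "stage_id", "day", "value"]],
        stage_order,
    )


# ---------------------------------------------------------------------------
# marker binning


def bin_cosegregating_markers(g: GenotypeTable) -> BinnedMarkers:
    """Collapse runs of adjacent identical genotype columns into bins.

    Identity is evaluated on the intersection of non-missing individuals,
    so two columns differing only through missingness are merged (logged).
    Bins never cross chromosome boundaries and partition the marker set.
    """
    if g.n_markers == 0:
        raise ValueError("empty genotype table")
    if g.n_individuals == 0:
        raise ValueError("genotype table has zero individuals")

    rows, reps = [], []
    chroms = g.markers["chromosome"].to_numpy()
    pos = g.markers["position_cM"].to_numpy()
    ids = g.markers["marker_id"].to_numpy()

    start = 0
    n_merged_via_missing = 0
    for m in range(1, g.n_markers + 1):
        new_bin = m == g.n_markers or chroms[m] != chroms[m - 1]
        if not new_bin:
            a, b = g.codes[m - 1], g.codes[m]
            both = ~(np.isnan(a) | np.isnan(b))
            if both.any() and np.array_equal(a[both], b[both]):
                if np.isnan(a).any() or np.isnan(b).any():
                    n_merged_via_missing += 1
            else:
                new_bin = True
        if new_bin:
            members = slice(start, m)
            # representative column: fill missing entries from other members
            rep = g.codes[members][0].copy()
            for row in g.codes[members][1:]:
                fill = np.isnan(rep) & ~np.isnan(row)
                rep[fill] = row[fill]
            rows.append(
                {
                    "bin_id": f"bin_{len(rows)}",
                    "chromosome": chroms[start],
                    "cM_min": float(np.min(pos[members])),
                    "cM_max": float(np.max(pos[members])),
                    "n_markers": m - start,
                    "member_marker_ids": list(ids[members]),
                }
            )
            reps.append(rep)
            start = m
    if n_merged_via_missing:
        logger.info(
            "bin_cosegregating_markers: %d merge(s) decided on the non-missing "
            "intersection of individuals", n_merged_via_missing,
        )
    return BinnedMarkers(pd.DataFrame(rows), list(g.individuals), np.asarray(reps))
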