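"""Plate normalization, replicate aggregation, and suppressor hit calling.

The screen design places siRNA library plates in gene-family order, so a
plate-mean normalization would be biased; instead activities are
normalized in two stages:

1. **position normalization** — each well value is divided by the mean of
   that grid position across all plates screened in the same batch (one
   screening day, typically 28-30 plates), removing systematic
   position effects (edge evaporation, dispensing gradients);
2. **control normalization** — each value is then expressed as a fraction
   of the plate's own negative-control wells (mutant construct with
   non-targeting siRNA), so 1 means "no change relative to control".

Replicate fractions are averaged per siRNA pool (arithmetic mean, SEM
with the n-1 sample SD).  A pool is a suppressor *hit* when its mean plus
SEM falls strictly below 1 - σ_screen, where σ_screen is the standard
deviation of all per-pool means in the entire screen.

Usage
-----
>>> model = SuppressorScreen(activities, manifest)
>>> res = model.fit()
>>> res.cutoff, len(res.hits)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ScreenError(ValueError):
    """Raised on invalid screen structure (empty batches, zero controls, ...)."""


# ---------------------------------------------------------------------------
# normalization primitives
# ---------------------------------------------------------------------------

def position_normalize(activities: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Divide each well value by its grid-position mean within the batch.

    Parameters
    ----------
    activities : DataFrame
        Columns plate_id, well, role, sirna_id, activity (one row per well).
    manifest : DataFrame
        Columns plate_id, batch_id, replicate_index; a batch is one
        screening day's set of plates.

    Returns
    -------
    DataFrame
        Input columns plus batch_id, replicate_index and ``normalized``
        (activity / per-position batch mean).  Control wells are included
        in the per-position averages: controls sit at fixed positions, so
        their position average is taken over like wells.
    """
    required = {"plate_id", "well", "activity"}
    if missing := required - set(activities.columns):
        raise ScreenError(f"activity table missing columns: {sorted(missing)}")
    man = manifest[["plate_id", "batch_id", "replicate_index"]]
    df = activities.merge(man, on="plate_id", how="left", validate="many_to_one")
    if df["batch_id"].isna().any():
        orphan = df.loc[df["batch_id"].isna(), "plate_id"].iloc[0]
        raise ScreenError(f"plate {orphan} missing from batch manifest")
    # all plates of a batch must share well geometry
    wells_per_plate = df.groupby(["batch_id", "plate_id"])["well"].agg(frozenset)
    for batch_id, per_plate in wells_per_plate.groupby(level="batch_id"):
        if per_plate.nunique() > 1:
            raise ScreenError(f"batch {batch_id}: plates have mixed well geometries")
    pos_mean = df.groupby(["batch_id", "well"])["activity"].transform("mean")
    zero = pos_mean == 0
    if zero.any():
        row = df[zero].iloc[0]
        raise ScreenError(
            f"zero per-position mean at batch {row.batch_id}, well {row.well}"
        )
    out = df.copy()
    out["normalized"] = df["activity"] / pos_mean
    return out


def control_normalize(plate: pd.DataFrame, value_col: str = "normalized") -> pd.DataFrame:
    """Express one plate's values as fractions of its negative-control mean.

    The reference is the arithmetic mean of the plate's ``neg_control``
    wells (mutant construct + non-targeting siRNA); their mean maps to 1.
    """
    neg = plate.loc[plate["role"] == "neg_control", value_col]
    if len(neg) == 0:
        raise ScreenError("plate has no neg_control wells")
    ref = neg.mean()
    if ref <= 0:
        raise ScreenError(f"nonpositive neg_control mean {ref}")
    out = plate.copy()
    out[value_col] = plate[value_col] / ref
    return out


def normalize_batches(activities: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Full two-stage normalization: position effects, then per-plate controls."""
    df = position_normalize(activities, manifest)
    return pd.concat(
        [control_normalize(grp) for _, grp in df.groupby("plate_id", sort=True)],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# aggregation and hit calling
# ---------------------------------------------------------------------------

def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and standard error of the mean of normalized replicate fractions.

    SEM uses the n-1 (sample) standard deviation divided by sqrt(n).
    Requires at least two replicates.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ScreenError(f"need >= 2 replicates, got {v.size}")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def screen_sd(means, ddof: int = 1) -> float:
    """Screen-wide standard deviation of per-siRNA normalized means.

    The sample (n-1) denominator is the default; at screen scale
    (thousands of pools) the population form differs negligibly, and the
    choice is exposed through ``ddof``.
    """
    m = np.asarray(means, dtype=float)
    if m.size < 2:
        raise ScreenError("need >= 2 per-siRNA means for a screen SD")
    return float(m.std(ddof=ddof))


def call_hits(records: pd.DataFrame, sigma: float) -> "ScreenResults":
    """Flag suppressor hits: mean + SEM strictly below 1 - sigma.

    Parameters
    ----------
    records : DataFrame
        Per-siRNA records with columns sirna_id, mean, sem (gene_id and n
        optional).
    sigma : float
        Screen-wide SD of normalized means, in (0, 1).

    Returns
    -------
    ScreenResults
        Hits are ranked ascending by mean (strongest suppression first).
        A symmetric ``enhancer`` convenience flag (mean - SEM > 1 + sigma)
        is attached but not analyzed further.
    """
    if not 0 < sigma < 1:
        raise ScreenError(f"screen SD {sigma} outside (0, 1)")
    rec = records.copy()
    if "gene_id" not in rec.columns:
        rec["gene_id"] = rec["sirna_id"]
    if "n" not in rec.columns:
        rec["n"] = np.nan
    cutoff = 1.0 - sigma
    rec["score"] = rec["mean"] + rec["sem"]
    rec["hit"] = rec["score"] < cutoff
    rec["enhancer"] = (rec["mean"] - rec["sem"]) > 1.0 + sigma
    rec = rec.sort_values(["mean", "sirna_id"]).reset_index(drop=True)
    return ScreenResults(records=rec, screen_sd=float(sigma), cutoff=float(cutoff))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class SuppressorScreen:
    """Suppressor-screen model over per-well activities.

    Parameters
    ----------
    activities : DataFrame
        Per-well activity table (plate_id, well, role, sirna_id,
        activity), e.g. from :func:`screensift.plate.quantify_plates`.
    manifest : DataFrame
        plate_id, batch_id, replicate_index mapping plates to screening
        days and replicate sets.
    gene_map : mapping, optional
        sirna_id -> gene_id; defaults to the identity (one pool per gene).
    min_replicates : int
        Minimum surviving replicates for a pool to be callable (failed
        wells are dropped pairwise); default 2.

    ``fit()`` runs normalization, aggregates replicates, estimates the
    screen-wide SD and returns a :class:`ScreenResults`.
    """

    def __init__(
        self,
        activities: pd.DataFrame,
        manifest: pd.DataFrame,
        gene_map: dict[str, str] | None = None,
        min_replicates: int = 2,
    ) -> None:
        self.activities = activities
        self.manifest = manifest
        self.gene_map = gene_map
        self.min_replicates = int(min_replicates)

    def fit(self, sd_override: float | None = None, sd_ddof: int = 1) -> "ScreenResults":
        """Normalize, aggregate, and call hits.

        Parameters
        ----------
        sd_override : float, optional
            Use this screen SD instead of estimating it from the data
            (e.g. a previously published screen-wide value).
        sd_ddof : int
            Delta degrees of freedom for the screen SD estimate.
        """
        norm = normalize_batches(self.activities, self.manifest)
        test = norm[(norm["role"] == "test") & (norm["sirna_id"] != "")]
        rows = []
        for sirna_id, grp in test.groupby("sirna_id", sort=True):
            vals = grp["normalized"].to_numpy()
            if vals.size < self.min_replicates or vals.size < 2:
                continue
            mean, sem = aggregate_replicates(vals)
            rows.append(
                {
                    "sirna_id": sirna_id,
                    "gene_id": self.gene_map.get(sirna_id, sirna_id)
                    if self.gene_map
                    else sirna_id,
                    "n": vals.size,
                    "mean": mean,
                    "sem": sem,
                }
            )
        if not rows:
            raise ScreenError("no callable siRNA records after normalization")
        records = pd.DataFrame(rows)
        sigma = sd_override if sd_override is not None else screen_sd(
            records["mean"], ddof=sd_ddof
        )
        res = call_hits(records, sigma)
        res.normalized = norm
        return res


@dataclass
class ScreenResults:
    """Results of a fitted suppressor screen.

    Attributes
    ----------
    records : DataFrame
        One row per siRNA pool: sirna_id, gene_id, n, mean, sem, score
        (mean + sem), hit, enhancer; sorted ascending by mean.
    screen_sd : float
        SD of per-pool normalized means across the screen.
    cutoff : float
        Hit-inclusion cutoff, 1 - screen_sd.
    """

    records: pd.DataFrame
    screen_sd: float
    cutoff: float
    normalized: pd.DataFrame | None = None

    @property
    def hits(self) -> pd.DataFrame:
        """Suppressor hits ranked by average magnitude of suppression."""
        return self.records[self.records["hit"]].reset_index(drop=True)

    @property
    def n_hits(self) -> int:
        return int(self.records["hit"].sum())

    def gene_rollup(self) -> pd.DataFrame:
        """Gene-level roll-up: minimum (mean + sem) across pools of a gene.

        Libraries may carry duplicate pools for one gene; the roll-up
        keeps each gene's best-supported (lowest-score) pool and re-flags
        hits at the same cutoff.
        """
        idx = self.records.groupby("gene_id")["score"].idxmin()
        out = self.records.loc[idx].sort_values(["mean", "gene_id"])
        return out.reset_index(drop=True)

    def summary(self) -> str:
        """Plain-text summary table of the screen fit."""
        rec = self.records
        lines = [
            "Suppressor screen results",
            "=" * 54,
            f"siRNA pools analyzed:    {len(rec)}",
            f"screen SD of means:      {self.screen_sd:.4f}",
            f"hit cutoff (1 - SD):     {self.cutoff:.4f}",
            f"suppressor hits:         {self.n_hits}",
            f"enhancer-flagged pools:  {int(rec['enhancer'].sum())}",
            "-" * 54,
            "top suppressors (mean +/- SEM, fraction of neg control):",
        ]
        for row in self.hits.head(10).itertuples(index=False):
            lines.append(
                f"  {row.sirna_id:<16s} {row.mean:6.3f} +/- {row.sem:5.3f}"
            )
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        cols = ["sirna_id", "gene_id", "n", "mean", "sem", "score", "hit", "enhancer"]
        self.records[cols].to_csv(path, sep="\t", index=False)
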