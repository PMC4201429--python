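"""Full analysis orchestration: groups x scales x indices, plus reporting.

``run_analysis`` takes a phylogeny, a capture-record table and a guild table
and, for every requested group (the overall assemblage and/or each guild) and
temporal scale: builds the presence-absence matrix, drops units with fewer
than two species (logged, so series keep their gaps), computes NRI and NTI
under the configured null model, classifies each unit's pattern, summarizes
pattern proportions, and runs the serial runs test on each chronological
index series.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    CommunityMatrix,
    SCALES,
    build_matrix,
    drop_degenerate_units,
    subset_guild,
)
from .null_models import NullConfig, ses_indices, with_seed
from .phylogeny import Phylogeny, node_count_distance_matrix
from .temporal_tests import SESSeries, series_tests

OVERALL = "overall"


@dataclass
class AnalysisConfig:
    """What to run and how."""

    scales: tuple[str, ...] = SCALES
    groups: Optional[tuple[str, ...]] = None  # None = overall + every guild present
    null: NullConfig = dc_field(default_factory=NullConfig)
    runs_reference: str = "zero"
    runs_method: str = "auto"
    alpha: float = 0.05
    min_richness: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.scales) - set(SCALES)
        if unknown:
            raise ValueError(f"unknown scales: {sorted(unknown)}")
        if not self.scales:
            raise ValueError("need at least one scale")


@dataclass
class AnalysisResult:
    ses_table: pd.DataFrame
    pattern_summary: pd.DataFrame
    runs_table: pd.DataFrame
    drop_log: pd.DataFrame
    metadata: dict

    def write(self, out_dir) -> None:
        """Write all tables and metadata; identical inputs give identical bytes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        self.ses_table.to_csv(out / "ses.tsv", **kw)
        self.pattern_summary.to_csv(out / "pattern_summary.tsv", **kw)
        self.runs_table.to_csv(out / "runs_tests.tsv", **kw)
        self.drop_log.to_csv(out / "dropped_units.tsv", **kw)
        (out / "run_metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True) + "\n"
        )


def _unit_seed(base_seed: int, group_i: int, scale_i: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(group_i, scale_i))
    return int(ss.generate_state(1)[0] % 2**31)


def run_analysis(
    phylo: Phylogeny,
    records: pd.DataFrame,
    guilds: pd.Series,
    config: AnalysisConfig,
) -> AnalysisResult:
    """Run the complete analysis grid and return all result tables."""
    record_species = set(records["species_id"].astype(str))
    missing = sorted(record_species - set(phylo.tip_labels))
    if missing:
        raise ValueError(f"species in records absent from the tree: {missing}")
    orphan_guilds = sorted(set(guilds.index) - record_species)
    if orphan_guilds:
        warnings.warn(
            f"{len(orphan_guilds)} guild-table species never captured; ignored",
            UserWarning, stacklevel=2)

    dist = node_count_distance_matrix(phylo)
    groups = config.groups
    if groups is None:
        present_guilds = [g for g in pd.unique(guilds.reindex(sorted(record_species)).dropna())
                          if g != "unclassified"]
        groups = (OVERALL, *sorted(present_guilds))

    ses_rows: list[dict] = []
    drop_rows: list[dict] = []
    series_list: list[SESSeries] = []
    for si, scale in enumerate(config.scales):
        full = build_matrix(records, scale)
        for gi, group in enumerate(groups):
            matrix = full if group == OVERALL else subset_guild(full, guilds, group)
            kept, dropped = drop_degenerate_units(matrix, config.min_richness)
            for unit in dropped:
                drop_rows.append({"group": group, "scale": scale, "unit": unit,
                                  "reason": f"richness < {config.min_richness}"})
            if kept.shape[0] == 0:
                series_list.extend(
                    SESSeries(scale, group, index, matrix.units,
                              [math.nan] * len(matrix.units))
                    for index in ("NRI", "NTI"))
                continue
            null = with_seed(config.null, _unit_seed(config.seed, gi, si))
            results = ses_indices(kept, dist, null)
            by_unit = {(r.unit, r.index): r for r in results}
            for r in results:
                ses_rows.append({
                    "group": group, "scale": scale, "unit": r.unit, "index": r.index,
                    "richness": r.richness, "observed": r.observed,
                    "null_mean": r.null_mean, "null_sd": r.null_sd, "ses": r.ses,
                    "rank": r.rank, "pattern": r.pattern,
                })
            for index in ("NRI", "NTI"):
                vals = []
                for unit in matrix.units:  # full chronology, gaps included
                    r = by_unit.get((unit, index))
                    vals.append(math.nan if r is None or r.pattern == "undefined" else r.ses)
                series_list.append(SESSeries(scale, group, index, matrix.units, vals))

    ses_table = pd.DataFrame(ses_rows)
    summary = summarize_patterns(ses_table)
    runs_table = series_tests(series_list, config.runs_reference, config.runs_method,
                              config.alpha)
    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "null_model": config.null.model,
        "n_rand": config.null.n_rand,
        "burn_in": config.null.burn_in,
        "thinning": config.null.thinning,
        "alpha": config.alpha,
        "scales": list(config.scales),
        "groups": list(groups),
        "runs_reference": config.runs_reference,
        "n_species": len(record_species),
        "n_tips": phylo.n_tips,
    }
    drop_log = pd.DataFrame(drop_rows, columns=["group", "scale", "unit", "reason"])
    return AnalysisResult(ses_table, summary, runs_table, drop_log, metadata)


def summarize_patterns(ses_table: pd.DataFrame) -> pd.DataFrame:
    """Pattern proportions per (group, scale, index) over defined units.

    Undefined units are excluded from the denominator and reported as
    ``n_undefined``; proportions sum to 1 for every row with tested units.
    """
    rows = []
    if len(ses_table) == 0:
        return pd.DataFrame(columns=["group", "scale", "index", "n_tested", "n_undefined",
                                     "prop_clustered", "prop_random", "prop_overdispersed"])
    for (group, scale, index), sub in ses_table.groupby(["group", "scale", "index"],
                                                        sort=False):
        defined = sub[sub["pattern"] != "undefined"]
        n = len(defined)
        row = {"group": group, "scale": scale, "index": index,
               "n_tested": n, "n_undefined": len(sub) - n}
        for pat in ("clustered", "random", "overdispersed"):
            row[f"prop_{pat}"] = (defined["pattern"] == pat).mean() if n else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
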