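"""Published reference tables bundled with the package.

Two kinds of tables from the S. bicolor BTx623 x S. halepense G9E study
ship as plain-text data: the genetic-map characteristics of the H4- and
H6-derived BC1F1 populations (one row per linkage group: marker count,
length, spacings, average AA/AB counts and their ratio), and the table of
genomic regions carrying runs of three or more consecutive S. propinquum
alleles in either population. They serve as worked-example inputs for the
summary-construction and run-bookkeeping logic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["map_summary", "propinquum_runs", "run_counts"]


def _data_path(name: str):
    return resources.files("tetramap").joinpath("data", name)


def map_summary(population: str) -> pd.DataFrame:
    """Published map characteristics table for 'h4' or 'h6'."""
    population = population.lower()
    if population not in ("h4", "h6"):
        raise ValueError(f"population must be 'h4' or 'h6', got {population!r}")
    with resources.as_file(_data_path(f"map_summary_{population}.csv")) as p:
        return pd.read_csv(p)


def propinquum_runs() -> pd.DataFrame:
    """Published table of S. propinquum allele runs in the two populations.

    Rows with empty H4 (or H6) coordinates are runs detected only in the
    other population.
    """
    with resources.as_file(_data_path("propinquum_runs.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def run_counts(runs: pd.DataFrame | None = None) -> dict[str, int]:
    """Bookkeeping of the run table: runs per population, shared and total."""
    if runs is None:
        runs = propinquum_runs()
    in_h4 = runs["h4_start"].notna()
    in_h6 = runs["h6_start"].notna()
    return {
        "n_h4": int(in_h4.sum()),
        "n_h6": int(in_h6.sum()),
        "n_shared": int((in_h4 & in_h6).sum()),
        "n_distinct": int(len(runs)),
    }
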