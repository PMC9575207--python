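"""Bundled reference tables and constants.

The package ships small published summary tables for the human and great-ape
pseudoautosomal region — per-branch divergence rates, per-population
population-genetic parameters (ρ, π, θ, Tajima's D, gBGC B, generation
times), divergence by recombination-rate bin — together with the analysis
constants (genetic map length 22.85 cM, sex-averaged 9.01 cM/Mb scaling,
trio-based yearly mutation rate, tercile cuts, window sizes). These serve as
inputs to the derivation steps (Ne, μ, fold comparisons) and as fixtures in
consistency checks.

Population codes: HUM human (YRI); PTE/PTS/PTT/PTV chimpanzee subspecies
(P. t. ellioti / schweinfurthii / troglodytes / verus); PPA bonobo;
GGG western lowland gorilla; PAB/PPY Sumatran and Bornean orangutan.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import pandas as pd

_PKG = "parevo.data"


def _path(name: str):
    return resources.files(_PKG).joinpath(name)


@lru_cache(maxsize=None)
def constants() -> dict:
    """Analysis constants (map length, scaling targets, window sizes ...)."""
    with _path("constants.json").open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def divergence_table() -> pd.DataFrame:
    """Per-branch total and per-site-and-year divergence for PAR1 and the
    concatenated autosomal telomeres (branches H, C, HC, G, HCG, O)."""
    with _path("par1_divergence.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@lru_cache(maxsize=None)
def population_table() -> pd.DataFrame:
    """Per-population PAR1 parameters: ρ (whole region), π, θ (PAR and
    autosomal), Tajima's D, gBGC strength B, generation time, and the
    published Ne / μ values they imply."""
    with _path("par1_population_params.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@lru_cache(maxsize=None)
def divergence_by_bin_table() -> pd.DataFrame:
    """Per-branch divergence split by low/medium/high recombination bin."""
    with _path("par1_divergence_by_bin.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
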