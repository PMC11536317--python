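"""Bundled reference tables.

Two groups of small TSVs ship with the package:

* ``published_{trait}_{set}.tsv`` — the published cross-reference tables
  for QTL validation: for each previously reported SNP (grouped into QTL
  codes) the p-value it obtained in the validation-set GWAS, and the best
  window candidate with its p-value, physical distance and LD r².
  Distances keep printed thousands separators; the LD column uses
  ``Same SNP`` for the distance-0 case and ``No`` when LD was not
  computable.
* variance-component presets (see :mod:`magicqtl.presets`) live in code.

Blank candidate cells on member rows mean the candidate reported for the
QTL's lead row spans the whole QTL block.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from ..core_io import PublishedQtl, read_published_qtls

TRAITS = ("tunnel_length", "grain_yield")
SETS = ("ivs", "hvs")


def _resource(trait: str, set_id: str):
    if trait not in TRAITS:
        raise KeyError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    if set_id not in SETS:
        raise KeyError(f"unknown set {set_id!r}; expected one of {SETS}")
    return resources.files("magicqtl.datasets") / f"published_{trait}_{set_id}.tsv"


def load_published_crossref(trait: str, set_id: str) -> pd.DataFrame:
    """Published-vs-validation cross-reference rows for one trait and set.

    Returns a DataFrame with columns: published_snp, qtl, published_p,
    candidate_snp, candidate_p, distance_bp (float, NaN on member rows),
    ld_r2 (float, NaN when not computable), ld_note (verbatim marker,
    'Same SNP' / 'No' / None).
    """
    with resources.as_file(_resource(trait, set_id)) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    df["published_p"] = df["published_p"].astype(float)
    df["candidate_p"] = df["candidate_p"].astype(float)
    df["distance_bp"] = (
        df["distance_bp"].str.replace(",", "", regex=False).astype(float)
    )
    notes = []
    r2 = []
    for raw in df["ld_r2"]:
        if isinstance(raw, str) and raw.strip() in ("Same SNP", "No"):
            notes.append(raw.strip())
            r2.append(math.nan)
        else:
            notes.append(None)
            r2.append(float(raw) if isinstance(raw, str) else math.nan)
    df["ld_r2"] = r2
    df["ld_note"] = notes
    return df


def load_published_qtls(trait: str, set_id: str = "ivs") -> list[PublishedQtl]:
    """The published QTL list (SNP members grouped by QTL code) for a trait."""
    with resources.as_file(_resource(trait, set_id)) as path:
        return read_published_qtls(path, trait=trait)
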