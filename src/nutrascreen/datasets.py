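"""Bundled reference tables and loaders.

The package ships the printed summary tables of the red-rice antidiabetic
study it reproduces, transcribed as plain CSV:

* ``study_panel.csv`` — the bioactivity panel: enzyme-inhibition IC50
  values, antioxidant capacities, glycation inhibition and phenolic /
  flavonoid totals for the four rice genotypes and the per-endpoint
  positive controls.  A ``source`` column records table and row of origin;
  the one non-detectable cell is the white-rice PTP1B entry.
* ``binding_energies.csv`` — docking energies (kcal/mol) of the ten
  docked metabolites against five glucose-regulatory targets, printed
  with the typographic minus sign, normalized on load.
* ``interactions.csv`` — the residue/bond-type interaction cells for the
  lead metabolites, verbatim, including the ``Nil`` cell.
* ``metabolites.csv`` — the identification list (names, classes,
  subclasses, per-genotype presence).  Only compounds named in the study
  text carry their real names; the remainder are clearly marked
  synthetic placeholders chosen so class/subclass counts and per-genotype
  identification totals match the published summary.  Retention times,
  m/z values, identification scores and abundances are synthetic (the
  underlying appendix tables are not public).
* ``descriptors_rrpm20.csv`` — a reconstructed descriptor table for the
  twenty abundant metabolites subjected to ADME screening: RDKit-computed
  physicochemical descriptors from the packaged structures plus a
  synthetic relative-abundance ranking in which the ten docked compounds
  lead the rule-compliant set.
* ``structures_rrpm20.smi`` — SMILES for the same twenty compounds, from
  which the descriptors can be recomputed.
"""

from __future__ import annotations

import importlib.resources as resources

import numpy as np
import pandas as pd

from .assay import AssayPanel
from .screening import MoleculeDescriptors

_UNICODE_MINUS = "−"


def _path(name: str):
    return resources.files("nutrascreen.data").joinpath(name)


def load_study_panel() -> AssayPanel:
    """The full bioactivity panel (enzyme, antioxidant and phenolic endpoints)."""
    with resources.as_file(_path("study_panel.csv")) as p:
        return AssayPanel.from_csv(p)


def load_enzyme_panel() -> AssayPanel:
    """IC50 endpoints of the four antihyperglycemic enzyme assays."""
    return load_study_panel().subset(
        ["amylase_ic50", "glucosidase_ic50", "dppiv_ic50", "ptp1b_ic50"]
    )


def load_antioxidant_panel() -> AssayPanel:
    """DPPH, FRAP, TEAC and AGEs-inhibition endpoints."""
    return load_study_panel().subset(["dpph_pct", "frap", "teac", "ages_pct"])


def load_binding_energies() -> pd.DataFrame:
    """Docking energies, compounds x targets, in kcal/mol (float)."""
    with resources.as_file(_path("binding_energies.csv")) as p:
        df = pd.read_csv(p)
    df = df.set_index("compound")
    for col in df.columns:
        df[col] = (
            df[col].astype(str).str.replace(_UNICODE_MINUS, "-", regex=False).astype(float)
        )
    return df


def load_interactions() -> pd.DataFrame:
    """Raw interaction cells: compound, target, raw_text."""
    with resources.as_file(_path("interactions.csv")) as p:
        return pd.read_csv(p)


def load_metabolites() -> pd.DataFrame:
    """The metabolite identification table (partially reconstructed)."""
    with resources.as_file(_path("metabolites.csv")) as p:
        return pd.read_csv(p)


def load_descriptors() -> tuple[list[MoleculeDescriptors], dict]:
    """Descriptor objects plus the relative-abundance map for the 20 RRPMs."""
    with resources.as_file(_path("descriptors_rrpm20.csv")) as p:
        df = pd.read_csv(p)
    descs = [
        MoleculeDescriptors(
            compound=row["compound"],
            mw=float(row["mw"]),
            logp=float(row["logp"]),
            hbd=int(row["hbd"]),
            hba=int(row["hba"]),
            tpsa=float(row["tpsa"]),
            wlogp=float(row["wlogp"]),
            charge_class=row["charge_class"],
        )
        for _, row in df.iterrows()
    ]
    abundance = dict(zip(df["compound"], df["abundance"].astype(float)))
    return descs, abundance


def load_structures() -> dict:
    """SMILES strings of the 20 screened metabolites, name -> SMILES."""
    out = {}
    with resources.as_file(_path("structures_rrpm20.smi")) as p:
        for line in p.read_text().splitlines():
            if line.strip():
                smi, name = line.split("\t", 1)
                out[name.strip()] = smi.strip()
    return out
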