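"""ADME screening and docking-table triage of candidate metabolites.

Drug-likeness filtering (Lipinski rule of five), gastrointestinal
absorption / brain penetration classification via the BOILED-Egg ellipse
model in (TPSA, WLOGP) space, the Abbott bioavailability score, and
post-processing of docking binding-energy and interaction tables: lead
selection by an energy threshold, best-binder lookup and residue/bond-type
parsing.

Docking energies are consumed, never computed — this module is a
post-processor for docking output tables.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ColumnError,
    IncompleteDescriptorError,
    IncompleteMatrixError,
    InteractionParseError,
    VocabularyError,
)

#: Fixed docking-target vocabulary.
TARGETS = ("amylase", "glucosidase", "dppiv", "ptp1b", "irs")

#: The Abbott bioavailability score takes one of exactly five values.
BIOAVAILABILITY_SCORES = (0.11, 0.17, 0.55, 0.56, 0.85)

#: Closed vocabulary of interaction bond types.
BOND_TYPES = (
    "conventional H bond",
    "carbon H bond",
    "pi-anion",
    "pi-cation",
    "pi-sigma",
    "pi-sulfur",
    "pi-pi stacked",
    "pi-pi T-shaped",
    "alkyl",
    "pi-alkyl",
    "pi-donor H bond",
    "halogen",
    "van der Waals",
)

# synonym -> canonical bond type (keys are lowercased, punctuation-stripped)
_BOND_SYNONYMS = {
    "h bond": "conventional H bond",
    "h bonds": "conventional H bond",
    "l h bond": "conventional H bond",
    "conv h bond": "conventional H bond",
    "conventional h bond": "conventional H bond",
    "conventional h bonds": "conventional H bond",
    "c h bond": "carbon H bond",
    "c h bonds": "carbon H bond",
    "carbon h bond": "carbon H bond",
    "pi anion": "pi-anion",
    "pi anion bond": "pi-anion",
    "pi cation": "pi-cation",
    "pi sigma": "pi-sigma",
    "pi sulfur": "pi-sulfur",
    "pi stacked": "pi-pi stacked",
    "pi pi stacked": "pi-pi stacked",
    "pi pi t shaped": "pi-pi T-shaped",
    "pi pi t shaped bond": "pi-pi T-shaped",
    "alkyl": "alkyl",
    "alkyl bond": "alkyl",
    "alkyl bonds": "alkyl",
    "alkyl interaction": "alkyl",
    "alkyl and c h bond": None,  # composite, handled by splitting
    "pi alkyl": "pi-alkyl",
    "pi alkyl bond": "pi-alkyl",
    "pi donor": "pi-donor H bond",
    "pi donor h bond": "pi-donor H bond",
    "pi donor bonds": "pi-donor H bond",
    "halogen": "halogen",
    "halogen fluorine": "halogen",
    "halogen fluorine bond": "halogen",
    "halogen (fluorine bond": "halogen",
    "fluorine bond": "halogen",
    "van der waal": "van der Waals",
    "van der waals": "van der Waals",
}


@dataclass
class MoleculeDescriptors:
    """Physicochemical descriptors used by the ADME screen.

    ``logp`` is the configurable screening lipophilicity (engines differ);
    ``wlogp`` is the atom-based value the BOILED-Egg model was fitted on.
    ``charge_class`` feeds the bioavailability score (``neutral``, ``acid``,
    ``base`` or ``zwitterion``).
    """

    compound: str
    mw: float
    logp: float
    hbd: int
    hba: int
    tpsa: float
    wlogp: float | None = None
    charge_class: str = "neutral"

    def __post_init__(self):
        for name in ("mw", "logp", "hbd", "hba", "tpsa"):
            if getattr(self, name) is None or (
                isinstance(getattr(self, name), float) and math.isnan(getattr(self, name))
            ):
                raise IncompleteDescriptorError(f"{self.compound}: missing descriptor {name!r}")
        if self.mw <= 0:
            raise ValueError(f"{self.compound}: mw must be positive")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError(f"{self.compound}: hbd/hba must be nonnegative")
        if self.tpsa < 0:
            raise ValueError(f"{self.compound}: tpsa must be nonnegative")
        if self.wlogp is None:
            self.wlogp = self.logp


@dataclass
class ScreenVerdict:
    """Outcome of the ADME screen for one molecule."""

    compound: str
    lipinski_pass: bool
    violations: list
    gi_absorption: str  # "high" | "low"
    bbb_permeant: bool
    bioavailability_score: float
    shortlisted: bool = False
    duplicate: bool = False


@dataclass
class EggEllipse:
    """A rotated ellipse in (TPSA, WLOGP) space."""

    center_tpsa: float
    center_wlogp: float
    width: float
    height: float
    angle_deg: float

    def contains(self, tpsa: float, wlogp: float) -> bool:
        t = math.radians(self.angle_deg)
        dx, dy = tpsa - self.center_tpsa, wlogp - self.center_wlogp
        u = dx * math.cos(t) + dy * math.sin(t)
        v = -dx * math.sin(t) + dy * math.cos(t)
        return (u / (self.width / 2)) ** 2 + (v / (self.height / 2)) ** 2 <= 1.0


#: Default ellipse coefficients of the published BOILED-Egg model
#: (white = high gastrointestinal absorption, yolk = brain penetration).
WHITE_ELLIPSE = EggEllipse(71.051, 2.292, 142.081, 8.740, -1.031325)
YOLK_ELLIPSE = EggEllipse(38.117, 3.177, 82.061, 5.557, -0.171887)


@dataclass
class BoiledEggResult:
    hia_high: bool
    bbb_permeant: bool

    @property
    def outside(self) -> bool:
        return not (self.hia_high or self.bbb_permeant)


@dataclass
class InteractionRecord:
    """A single residue/bond-type contact between a ligand and a target."""

    compound: str
    target: str
    residue: str  # e.g. "GLU233"
    bond_type: str

    def __post_init__(self):
        if not re.fullmatch(r"[A-Z]{3}[0-9]+", self.residue):
            raise InteractionParseError(f"malformed residue token {self.residue!r}")
        if self.bond_type not in BOND_TYPES:
            raise VocabularyError(f"unknown bond type {self.bond_type!r}")


# ---------------------------------------------------------------------------
# ADME screen
# ---------------------------------------------------------------------------

def lipinski_screen(desc: MoleculeDescriptors) -> tuple[bool, list]:
    """Rule-of-five check: MW <= 500 Da, logP <= 5, HBD <= 5, HBA <= 10.

    Thresholds are inclusive (the classic rule): a molecule with exactly
    five H-bond donors, such as catechin, is compliant.  Returns
    ``(pass, violations)`` where pass requires zero violations.
    """
    violations = []
    if desc.mw > 500:
        violations.append("mw")
    if desc.logp > 5:
        violations.append("logp")
    if desc.hbd > 5:
        violations.append("hbd")
    if desc.hba > 10:
        violations.append("hba")
    return len(violations) == 0, violations


def boiled_egg(
    tpsa: float,
    wlogp: float,
    white: EggEllipse = WHITE_ELLIPSE,
    yolk: EggEllipse = YOLK_ELLIPSE,
) -> BoiledEggResult:
    """Classify a molecule by the BOILED-Egg ellipses.

    The white ellipse predicts high gastrointestinal absorption, the yolk
    predicts blood-brain-barrier permeation; a point may fall in both.
    """
    if tpsa < 0:
        raise ValueError("tpsa must be nonnegative")
    return BoiledEggResult(
        hia_high=white.contains(tpsa, wlogp),
        bbb_permeant=yolk.contains(tpsa, wlogp),
    )


def bioavailability_score(desc: MoleculeDescriptors) -> float:
    """Abbott (rule-based) oral bioavailability score.

    Anions are scored on polar surface area (TPSA <= 75 -> 0.85,
    75 < TPSA <= 150 -> 0.56, else 0.11); all other charge classes score
    0.55 when they carry at most one rule-of-five violation and 0.17
    otherwise.
    """
    if desc.charge_class not in {"neutral", "acid", "base", "zwitterion"}:
        raise VocabularyError(
            f"unknown charge_class {desc.charge_class!r}; "
            "expected neutral|acid|base|zwitterion"
        )
    if desc.charge_class == "acid":
        if desc.tpsa <= 75:
            return 0.85
        if desc.tpsa <= 150:
            return 0.56
        return 0.11
    _, violations = lipinski_screen(desc)
    return 0.55 if len(violations) <= 1 else 0.17


def screen_candidates(
    descs,
    min_bioavailability: float = 0.55,
    abundance: dict | None = None,
    top_n: int | None = None,
) -> tuple[list[ScreenVerdict], list[str]]:
    """Screen molecules and shortlist docking candidates.

    A molecule is rule-compliant when it passes Lipinski, is predicted to
    have high GI absorption and reaches ``min_bioavailability``.  When an
    ``abundance`` map and ``top_n`` are given the shortlist keeps only the
    ``top_n`` most abundant compliant molecules — mirroring workflows that
    dock the most abundant drug-like constituents of an extract.

    Descriptor errors are recorded per molecule; remaining molecules are
    still screened.
    """
    if not descs:
        return [], []
    verdicts: list[ScreenVerdict] = []
    seen = set()
    for desc in descs:
        duplicate = desc.compound in seen
        seen.add(desc.compound)
        lip_pass, violations = lipinski_screen(desc)
        egg = boiled_egg(desc.tpsa, desc.wlogp)
        score = bioavailability_score(desc)
        compliant = lip_pass and egg.hia_high and score >= min_bioavailability
        verdicts.append(
            ScreenVerdict(
                compound=desc.compound,
                lipinski_pass=lip_pass,
                violations=violations,
                gi_absorption="high" if egg.hia_high else "low",
                bbb_permeant=egg.bbb_permeant,
                bioavailability_score=score,
                shortlisted=compliant and not duplicate,
                duplicate=duplicate,
            )
        )
    shortlist = [v.compound for v in verdicts if v.shortlisted]
    if abundance is not None and top_n is not None and len(shortlist) > top_n:
        ranked = sorted(shortlist, key=lambda c: (-abundance.get(c, 0.0), c))
        keep = set(ranked[:top_n])
        for v in verdicts:
            if v.shortlisted and v.compound not in keep:
                v.shortlisted = False
        shortlist = [c for c in shortlist if c in keep]
    return verdicts, shortlist


def descriptors_from_smiles(compound: str, smiles: str, charge_class: str = "neutral") -> MoleculeDescriptors:
    """Compute screening descriptors from a SMILES string with RDKit.

    ``logp`` and ``wlogp`` both use the Crippen atom-contribution model,
    the same family the BOILED-Egg ellipses were fitted on.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise IncompleteDescriptorError(f"{compound}: unparseable SMILES {smiles!r}")
    wlogp = float(Crippen.MolLogP(mol))
    return MoleculeDescriptors(
        compound=compound,
        mw=float(Descriptors.MolWt(mol)),
        logp=wlogp,
        hbd=int(rdMolDescriptors.CalcNumHBD(mol)),
        hba=int(rdMolDescriptors.CalcNumHBA(mol)),
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        wlogp=wlogp,
        charge_class=charge_class,
    )


# ---------------------------------------------------------------------------
# docking-table triage
# ---------------------------------------------------------------------------

def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.index.duplicated().any():
        raise ValueError("duplicate compounds in binding-energy matrix")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        return matrix  # NaN handled by callers per policy
    return matrix


def select_leads(
    matrix: pd.DataFrame,
    threshold: float = -6.0,
    require_all: bool = True,
    min_targets: int | None = None,
) -> list[str]:
    """Compounds binding at or below ``threshold`` kcal/mol.

    With ``require_all`` every target column must satisfy the threshold;
    otherwise at least ``min_targets`` columns must.  Energies are
    kcal/mol, more negative meaning stronger binding, so the comparison is
    ``energy <= threshold``.
    """
    _check_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    if require_all:
        if np.isnan(values).any():
            raise IncompleteMatrixError(
                "binding-energy matrix has missing entries under require_all"
            )
        mask = (values <= threshold).all(axis=1)
    else:
        k = min_targets if min_targets is not None else 1
        mask = (np.nan_to_num(values, nan=np.inf) <= threshold).sum(axis=1) >= k
    return [str(c) for c in matrix.index[mask]]


def best_binder(matrix: pd.DataFrame, target: str) -> tuple[str, float, bool]:
    """Row with the minimum (strongest) energy for a target column.

    Returns ``(compound, energy, tied)``; ties break lexicographically.
    """
    if target not in matrix.columns:
        raise ColumnError(f"unknown target {target!r}; columns: {list(matrix.columns)}")
    col = matrix[target].astype(float).dropna()
    if col.empty:
        raise IncompleteMatrixError(f"no energies for target {target!r}")
    best = col.min()
    holders = sorted(str(c) for c in col.index[col == best])
    return holders[0], float(best), len(holders) > 1


_RESIDUE_RE = re.compile(r"\b([A-Z]{3})\s?(\d+)\b")


def _normalize_bond_token(token: str) -> list[str]:
    cleaned = re.sub(r"[().&/-]", " ", token).lower()
    cleaned = re.sub(r"\s+", " ", cleaned).strip()
    if not cleaned:
        return []
    if " and " in f" {cleaned} " or " & " in f" {token.lower()} ":
        parts = re.split(r"\band\b|&", cleaned)
        out = []
        for part in parts:
            out.extend(_normalize_bond_token(part))
        return out
    # drop trailing pluralisation and the filler word "interaction(s)"
    cleaned = re.sub(r"\binteractions?\b", "bond", cleaned).strip()
    for key in (cleaned, cleaned.rstrip("s"), cleaned + " bond"):
        canon = _BOND_SYNONYMS.get(key)
        if canon:
            return [canon]
    raise InteractionParseError(f"unknown bond-type token {token!r}")


def parse_interactions(raw_text: str, compound: str = "", target: str = "") -> list[InteractionRecord]:
    """Parse a grouped residue/bond-type cell into interaction records.

    The input format is the docking-report convention
    ``"RES1, RES2 (bond type), RES3 (other type)"`` — residues accumulate
    until a parenthesised bond descriptor assigns them a type (possibly
    several, joined by ``&``).  The literal token ``Nil`` yields no records.
    """
    text = str(raw_text).strip()
    if not text or text.lower() == "nil":
        return []
    # linearise unbalanced nesting: a second "(" opened inside a group (a
    # printing artefact like "(halogen (fluorine bond)") becomes a space
    chars, in_group = [], False
    for ch in text:
        if ch == "(":
            chars.append(" " if in_group else "(")
            in_group = True
        elif ch == ")":
            chars.append(")" if in_group else " ")
            in_group = False
        else:
            chars.append(ch)
    text = "".join(chars)
    records: list[InteractionRecord] = []
    pending: list[str] = []
    pos = 0
    while pos < len(text):
        open_idx = text.find("(", pos)
        chunk = text[pos:] if open_idx == -1 else text[pos:open_idx]
        for m in _RESIDUE_RE.finditer(chunk):
            pending.append(m.group(1) + m.group(2))
        leftover = _RESIDUE_RE.sub("", chunk).strip(" ,;")
        if leftover and not re.fullmatch(r"[\s,;]*", leftover):
            # words like "RESIDUES" between tokens are tolerated silently
            if not re.fullmatch(r"(?i)[\s,;]*(residues?)?[\s,;]*", leftover):
                raise InteractionParseError(
                    f"unrecognised text {leftover!r} in row {text!r}"
                )
        if open_idx == -1:
            break
        close_idx = text.find(")", open_idx)
        if close_idx == -1:
            close_idx = len(text)  # unbalanced: take the rest
        bond_text = text[open_idx + 1 : close_idx]
        bond_types = []
        for part in re.split(r",|&|\band\b", bond_text):
            bond_types.extend(_normalize_bond_token(part))
        # de-duplicate while keeping order
        bond_types = list(dict.fromkeys(bond_types))
        if bond_types and not pending:
            # stray group with no residues: ignore (seen in printed tables)
            pass
        for residue in pending:
            for bt in bond_types:
                records.append(
                    InteractionRecord(
                        compound=compound, target=target, residue=residue, bond_type=bt
                    )
                )
        pending = []
        pos = close_idx + 1
    return records


def serialize_interactions(records) -> str:
    """Inverse of :func:`parse_interactions` for well-formed rows."""
    if not records:
        return "Nil"
    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(rec.bond_type, []).append(rec.residue)
    parts = []
    for bond_type, residues in groups.items():
        label = "H bond" if bond_type == "conventional H bond" else bond_type
        parts.append(f"{', '.join(dict.fromkeys(residues))} ({label})")
    return ", ".join(parts)


def count_by_bond_type(records) -> pd.Series:
    """Aggregate interaction records into counts per bond type."""
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.bond_type] = counts.get(rec.bond_type, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
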