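"""The 61-feature characterization of a protein pair.

Feature groups, in registry order:

* 3 GO-term similarities (biological process, molecular function, cellular
  component), Jaccard over direct annotations by default;
* 4 orthologous-interaction flags (M. musculus, D. melanogaster,
  S. cerevisiae, E. coli);
* 4 presence-in-other-database flags (MINT, APID, BIOGRID plus a
  configurable fourth source);
* 1 sequence-similarity E-value (consumed from a precomputed pairwise
  alignment-search table);
* 1 Pfam domain-domain interaction flag;
* 1 subcellular co-localization flag;
* 17 Spearman co-expression correlations, one per expression dataset;
* 30 absolute physicochemical differences (the 20 amino-acid percentage
  differences plus molecular weight, aromaticity, instability, the
  helix/turn/sheet fractions, both molar extinction coefficients, GRAVY
  and charge at pH 7).

Every feature is symmetric in the pair and carries an explicit missingness
flag; nothing is silently imputed at feature time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.stats import spearmanr

from .interactions import EvalueTable, canonical_pair

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GO_ASPECTS = ("BP", "MF", "CC")
ORTHOLOGY_ORGANISMS = ("M_musculus", "D_melanogaster", "S_cerevisiae", "E_coli")
DEFAULT_DB_FLAGS = ("MINT", "APID", "BIOGRID", "DB4")

#: The 17 expression datasets contributing one Spearman feature each.
EXPRESSION_DATASETS = (
    "GDS531", "GDS534", "GDS596", "GDS651", "GDS806", "GDS807", "GDS843",
    "GDS987", "GDS1085", "GDS2855", "GDS1402", "GDS181", "GDS1088",
    "GDS841", "GDS3257", "GSE227375", "GSE228702",
)

PHYSCHEM_KEYS = (
    "mw", "aromaticity", "instability", "helix_frac", "turn_frac",
    "sheet_frac", "eps_reduced", "eps_cystines", "gravy", "charge_pH7",
)
_PHYSCHEM_DIFF_NAMES = (
    "mw_dif", "aromaticity_dif", "instability_dif", "helix_dif", "turn_dif",
    "sheet_dif", "cys_reduced_dif", "cys_cystines_dif", "gravy_dif",
    "charge_pH7_dif",
)

# Secondary-structure residue classes (classical convention).
HELIX_RESIDUES = frozenset("VIYFWL")
TURN_RESIDUES = frozenset("NPGS")
SHEET_RESIDUES = frozenset("EMAL")

# EMBOSS pKa values for the Henderson-Hasselbalch charge at a given pH.
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
_POSITIVE_GROUPS = ("Nterm", "K", "R", "H")
_NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")


def feature_registry(
    db4_label: str = "DB4",
    expression_datasets: tuple[str, ...] = EXPRESSION_DATASETS,
) -> tuple[str, ...]:
    """The fixed, ordered tuple of feature names (61 by default).

    ``expression_datasets`` sets the co-expression features, one per
    dataset; the default 17 give the canonical 61-feature registry, and a
    longer tuple (e.g. appending the two RNA-seq series as separate
    features) extends it.
    """
    names = ["BP_similarity", "MF_similarity", "CC_similarity"]
    names += [f"Ortho_{org}" for org in ORTHOLOGY_ORGANISMS]
    names += [f"Exists in {db}?" for db in ("MINT", "APID", "BIOGRID", db4_label)]
    names += ["Sequence Similarity", "pfam_interaction", "co_localization"]
    names += [f"Spearman_{ds}" for ds in expression_datasets]
    names += [f"{aa} %" for aa in AMINO_ACIDS]
    names += list(_PHYSCHEM_DIFF_NAMES)
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = feature_registry()
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 61


class InvalidSequenceError(ValueError):
    pass


@dataclass
class ProteinAnnotation:
    """Everything known about one protein that the feature engine consumes."""

    accession: str
    sequence: str
    go_terms: dict[str, set[str]] = field(default_factory=dict)  # aspect -> terms
    pfam_domains: set[str] = field(default_factory=set)
    localizations: set[str] | None = None
    expression: dict[str, np.ndarray] = field(default_factory=dict)  # dataset -> vector


@dataclass
class FeatureVector:
    values: np.ndarray  # float, NaN where missing
    missing_mask: np.ndarray  # bool
    names: tuple[str, ...] = FEATURE_NAMES

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise InvalidSequenceError(f"invalid residue {ch!r} at position {i}")
    return seq


def aa_composition(sequence: str) -> dict[str, float]:
    """Fractional composition over the 20 canonical residues (sums to 1)."""
    seq = _validate_sequence(sequence)
    n = len(seq)
    return {aa: seq.count(aa) / n for aa in AMINO_ACIDS}


def secondary_structure_fractions(
    sequence: str,
    helix: frozenset[str] = HELIX_RESIDUES,
    turn: frozenset[str] = TURN_RESIDUES,
    sheet: frozenset[str] = SHEET_RESIDUES,
) -> tuple[float, float, float]:
    """Fractions of residues in the helix/turn/sheet-favouring classes."""
    seq = _validate_sequence(sequence)
    n = len(seq)
    return (
        sum(seq.count(r) for r in helix) / n,
        sum(seq.count(r) for r in turn) / n,
        sum(seq.count(r) for r in sheet) / n,
    )


def charge_at_pH(sequence: str, ph: float = 7.0,
                 pka: dict[str, float] = EMBOSS_PKA) -> float:
    """Net protein charge from Henderson-Hasselbalch over a pKa table."""
    seq = _validate_sequence(sequence)
    counts = {aa: seq.count(aa) for aa in AMINO_ACIDS}
    counts["Nterm"] = counts["Cterm"] = 1
    charge = 0.0
    for grp in _POSITIVE_GROUPS:
        charge += counts.get(grp, 0) / (1.0 + 10 ** (ph - pka[grp]))
    for grp in _NEGATIVE_GROUPS:
        charge -= counts.get(grp, 0) / (1.0 + 10 ** (pka[grp] - ph))
    return charge


def physchem_profile(sequence: str) -> dict[str, float | None]:
    """The ten scalar physicochemical descriptors of one sequence.

    Molecular weight, aromaticity, GRAVY, the instability index and the
    molar extinction coefficients follow the standard ProtParam
    definitions; instability is undefined (``None``) for single-residue
    sequences.
    """
    seq = _validate_sequence(sequence)
    pa = ProteinAnalysis(seq)
    helix, turn, sheet = secondary_structure_fractions(seq)
    eps_reduced, eps_cystines = pa.molar_extinction_coefficient()
    return {
        "mw": pa.molecular_weight(),
        "aromaticity": pa.aromaticity(),
        "instability": pa.instability_index() if len(seq) >= 2 else None,
        "helix_frac": helix,
        "turn_frac": turn,
        "sheet_frac": sheet,
        "eps_reduced": float(eps_reduced),
        "eps_cystines": float(eps_cystines),
        "gravy": pa.gravy(),
        "charge_pH7": charge_at_pH(seq, 7.0),
    }


def pair_difference(
    profile_a: dict[str, float | None], profile_b: dict[str, float | None],
    composition_a: dict[str, float], composition_b: dict[str, float],
) -> dict[str, float | None]:
    """The 30 absolute differences; ``None`` propagates from either side."""
    out: dict[str, float | None] = {}
    for aa in AMINO_ACIDS:
        out[f"{aa} %"] = abs(composition_a[aa] - composition_b[aa])
    for key, name in zip(PHYSCHEM_KEYS, _PHYSCHEM_DIFF_NAMES):
        va, vb = profile_a[key], profile_b[key]
        out[name] = None if va is None or vb is None else abs(va - vb)
    return out


def go_similarity(terms_a: set[str], terms_b: set[str], measure=None) -> float | None:
    """Similarity of two direct-annotation term sets in [0, 1].

    Default measure is the Jaccard index; an alternative callable
    ``measure(terms_a, terms_b) -> float`` (e.g. an information-content
    similarity) may be plugged in. Both sets empty -> missing.
    """
    if not terms_a and not terms_b:
        return None
    if measure is not None:
        return float(measure(terms_a, terms_b))
    union = terms_a | terms_b
    return len(terms_a & terms_b) / len(union)


def lookup_flags(pair: tuple[str, str], tables: dict[str, set[tuple[str, str]]],
                 order: tuple[str, ...]) -> dict[str, int]:
    """Presence of the unordered pair in each keyed pair-set table."""
    key = canonical_pair(*pair)
    return {name: int(key in tables.get(name, set())) for name in order}


def pfam_interaction(domains_a: set[str], domains_b: set[str],
                     ddi_table: set[tuple[str, str]]) -> int:
    """1 iff some domain of a and some domain of b form a known DDI pair."""
    for da in domains_a:
        for db in domains_b:
            if canonical_pair(da, db) in ddi_table:
                return 1
    return 0


def colocalization(loc_a: set[str] | None, loc_b: set[str] | None) -> int | None:
    """1 iff compartment sets intersect; missing when either is unknown."""
    if loc_a is None or loc_b is None:
        return None
    return int(bool(loc_a & loc_b))


def expression_correlation(x: np.ndarray | None, y: np.ndarray | None) -> float | None:
    """Spearman rho of two expression vectors; missing when undefined."""
    if x is None or y is None:
        return None
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # constant vector, rho undefined
        return None
    rho = spearmanr(x, y).statistic
    return None if math.isnan(rho) else float(rho)


def expression_correlations(
    annot_a: ProteinAnnotation, annot_b: ProteinAnnotation,
    datasets: tuple[str, ...] = EXPRESSION_DATASETS,
) -> dict[str, float | None]:
    return {
        ds: expression_correlation(annot_a.expression.get(ds), annot_b.expression.get(ds))
        for ds in datasets
    }


@dataclass
class FeatureResources:
    """Reference tables required by :func:`assemble_feature_vector`."""

    annotations: dict[str, ProteinAnnotation]
    orthology: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    databases: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    ddi: set[tuple[str, str]] = field(default_factory=set)
    evalues: EvalueTable = field(default_factory=EvalueTable)
    db4_label: str = "DB4"
    expression_datasets: tuple[str, ...] = EXPRESSION_DATASETS


def assemble_feature_vector(pair: tuple[str, str], resources: FeatureResources) -> FeatureVector:
    """Compute the full named feature vector for one unordered pair.

    Sequences are mandatory (hard error when absent); every other resource
    is optional and unresolvable features are flagged missing.
    """
    a, b = canonical_pair(*pair)
    try:
        annot_a, annot_b = resources.annotations[a], resources.annotations[b]
    except KeyError as exc:
        raise KeyError(f"no sequence/annotation for protein {exc.args[0]}") from None

    values: dict[str, float | None] = {}
    for aspect, name in zip(GO_ASPECTS, ("BP_similarity", "MF_similarity", "CC_similarity")):
        values[name] = go_similarity(
            annot_a.go_terms.get(aspect, set()), annot_b.go_terms.get(aspect, set())
        )
    for org in ORTHOLOGY_ORGANISMS:
        values[f"Ortho_{org}"] = int(canonical_pair(a, b) in resources.orthology.get(org, set()))
    for db in ("MINT", "APID", "BIOGRID", resources.db4_label):
        values[f"Exists in {db}?"] = int(
            canonical_pair(a, b) in resources.databases.get(db, set())
        )
    values["Sequence Similarity"] = resources.evalues.get(a, b)
    values["pfam_interaction"] = pfam_interaction(
        annot_a.pfam_domains, annot_b.pfam_domains, resources.ddi
    )
    values["co_localization"] = colocalization(annot_a.localizations, annot_b.localizations)
    values.update(
        {f"Spearman_{ds}": rho for ds, rho in
         expression_correlations(annot_a, annot_b, resources.expression_datasets).items()}
    )
    comp_a, comp_b = aa_composition(annot_a.sequence), aa_composition(annot_b.sequence)
    prof_a, prof_b = physchem_profile(annot_a.sequence), physchem_profile(annot_b.sequence)
    values.update(pair_difference(prof_a, prof_b, comp_a, comp_b))

    names = feature_registry(resources.db4_label, resources.expression_datasets)
    arr = np.array([np.nan if values[n] is None else float(values[n]) for n in names])
    return FeatureVector(values=arr, missing_mask=np.isnan(arr), names=names)


def compute_feature_matrix(
    pairs: list[tuple[str, str]], resources: FeatureResources
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature matrix and parallel missingness matrix, indexed by pair key."""
    rows, masks, index = [], [], []
    names = list(feature_registry(resources.db4_label, resources.expression_datasets))
    for pair in pairs:
        fv = assemble_feature_vector(pair, resources)
        rows.append(fv.values)
        masks.append(fv.missing_mask)
        index.append("|".join(canonical_pair(*pair)))
    X = pd.DataFrame(rows, columns=names, index=index)
    M = pd.DataFrame(masks, columns=names, index=index)
    return X, M


def write_feature_matrix(X: pd.DataFrame, M: pd.DataFrame, path) -> None:
    X.to_csv(path, sep="\t", index_label="pair")
    M.astype(int).to_csv(str(path) + ".missing.tsv", sep="\t", index_label="pair")
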