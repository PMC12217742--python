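"""Synthetic worlds with planted interaction signal.

Generates a proteome (random sequences with realistic residue
frequencies), GO/Pfam/localization/expression annotations and labelled
interaction pairs such that planted-positive pairs carry elevated
similarity and co-expression in a declared subset of the 61 features.
Every other module is testable against these worlds without downloads:
the writers emit MITAB-dialect interaction tables, negative lists, FASTA,
annotation TSVs, expression matrices, E-value tables, affinity tables
(with curation decoys) and a ground-truth manifest. Generation is
bit-reproducible under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from .affinity import k_from_delta_g
from .features import EXPRESSION_DATASETS, FeatureResources, ProteinAnnotation
from .interactions import EvalueTable, InteractionRecord, canonical_pair

#: Residue sampling frequencies (approximate natural abundances).
RESIDUE_FREQUENCIES = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}

#: Default planted-signal strengths: probability that a true-positive pair
#: receives the corresponding enrichment. Exactly five informative
#: features; everything else carries no label signal.
DEFAULT_EFFECT_SIZES = {
    "BP_similarity": 0.7,
    "MF_similarity": 0.7,
    "pfam_interaction": 0.7,
    "co_localization": 0.7,
    "Spearman_GDS531": 0.8,
}

#: Linear map from planted pair features to the binding free energy.
DEFAULT_AFFINITY_RULE = {
    "intercept": -20.0,
    "MF_similarity": -25.0,
    "pfam_interaction": -8.0,
    "co_localization": -5.0,
}

_POSITIVE_METHODS = ("two hybrid", "tandem affinity purification")


@dataclass
class SyntheticWorld:
    proteins: dict[str, ProteinAnnotation]
    true_positives: list[tuple[str, str]]
    true_negatives: list[tuple[str, str]]
    records: list[InteractionRecord]  # labels after noise flips
    resources: FeatureResources
    effect_sizes: dict[str, float]
    noise: float
    seed: int
    affinity_rule: dict[str, float] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def accessions(self) -> list[str]:
        return list(self.proteins)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def pairs(self) -> list[tuple[str, str]]:
        return [r.pair for r in self.records]

    def feature_matrix(self) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
        """(features, missingness, labels) for every labelled pair."""
        X, M = ft.compute_feature_matrix(self.pairs(), self.resources)
        return X, M, self.labels()


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    aas = list(RESIDUE_FREQUENCIES)
    p = np.array([RESIDUE_FREQUENCIES[a] for a in aas])
    p = p / p.sum()
    return "".join(rng.choice(aas, size=length, p=p))


def _informative_pair_features(pair, resources) -> dict[str, float]:
    """The planted features the affinity rule may consume."""
    a, b = canonical_pair(*pair)
    annot_a, annot_b = resources.annotations[a], resources.annotations[b]
    return {
        "BP_similarity": ft.go_similarity(annot_a.go_terms.get("BP", set()),
                                          annot_b.go_terms.get("BP", set())) or 0.0,
        "MF_similarity": ft.go_similarity(annot_a.go_terms.get("MF", set()),
                                          annot_b.go_terms.get("MF", set())) or 0.0,
        "pfam_interaction": ft.pfam_interaction(annot_a.pfam_domains,
                                                annot_b.pfam_domains, resources.ddi),
        "co_localization": ft.colocalization(annot_a.localizations,
                                             annot_b.localizations) or 0,
    }


def generate_world(
    n_proteins: int = 300,
    n_positive: int = 200,
    n_negative: int = 400,
    effect_sizes: dict[str, float] | None = None,
    noise: float = 0.05,
    seed: int = 0,
    n_expression_samples: int = 10,
    expression_datasets: tuple[str, ...] = EXPRESSION_DATASETS,
) -> SyntheticWorld:
    """Plant a labelled interaction world with tunable feature signal."""
    if n_positive + n_negative > n_proteins * (n_proteins - 1) // 2:
        raise ValueError("more pairs requested than distinct unordered pairs exist")
    effect_sizes = DEFAULT_EFFECT_SIZES if effect_sizes is None else dict(effect_sizes)
    rng = np.random.default_rng(seed)

    accessions = [f"P{10000 + i}" for i in range(n_proteins)]
    proteins: dict[str, ProteinAnnotation] = {}
    go_pools = {asp: [f"GO:{asp}{i:04d}" for i in range(120)] for asp in ft.GO_ASPECTS}
    domain_pool = [f"PF{i:05d}" for i in range(80)]
    compartments = [f"compartment_{i}" for i in range(8)]
    for acc in accessions:
        length = int(rng.integers(50, 351))
        proteins[acc] = ProteinAnnotation(
            accession=acc,
            sequence=_random_sequence(rng, length),
            go_terms={asp: set(rng.choice(go_pools[asp], size=int(rng.integers(4, 9)),
                                          replace=False))
                      for asp in ft.GO_ASPECTS},
            pfam_domains=set(rng.choice(domain_pool, size=int(rng.integers(1, 4)),
                                        replace=False)),
            localizations=set(rng.choice(compartments, size=int(rng.integers(1, 3)),
                                         replace=False)),
            expression={ds: rng.normal(size=n_expression_samples)
                        for ds in expression_datasets},
        )

    # Sample disjoint positive/negative pairs.
    chosen: set[tuple[str, str]] = set()
    def sample_pairs(k: int) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        while len(out) < k:
            i, j = rng.integers(0, n_proteins, size=2)
            if i == j:
                continue
            pair = canonical_pair(accessions[i], accessions[j])
            if pair not in chosen:
                chosen.add(pair)
                out.append(pair)
        return out

    positives = sample_pairs(n_positive)
    negatives = sample_pairs(n_negative)

    # Baseline domain-domain interaction table (uninformative background).
    ddi: set[tuple[str, str]] = set()
    while len(ddi) < 40:
        d1, d2 = rng.choice(domain_pool, size=2, replace=False)
        ddi.add(canonical_pair(d1, d2))

    # Plant the signal on the true positives.
    expr_effects = {k.removeprefix("Spearman_"): v for k, v in effect_sizes.items()
                    if k.startswith("Spearman_")}
    for a, b in positives:
        pa, pb = proteins[a], proteins[b]
        for aspect, fname in zip(ft.GO_ASPECTS,
                                 ("BP_similarity", "MF_similarity", "CC_similarity")):
            if rng.random() < effect_sizes.get(fname, 0.0):
                shared = rng.choice(sorted(pa.go_terms[aspect]),
                                    size=max(1, len(pa.go_terms[aspect]) // 2),
                                    replace=False)
                keep = rng.choice(sorted(pb.go_terms[aspect]),
                                  size=len(pb.go_terms[aspect]) // 2, replace=False)
                pb.go_terms[aspect] = set(shared) | set(keep)
        if rng.random() < effect_sizes.get("pfam_interaction", 0.0):
            da = rng.choice(sorted(pa.pfam_domains))
            db = rng.choice(sorted(pb.pfam_domains))
            ddi.add(canonical_pair(str(da), str(db)))
        if rng.random() < effect_sizes.get("co_localization", 0.0):
            pb.localizations.add(sorted(pa.localizations)[0])
        for ds, effect in expr_effects.items():
            if ds in pa.expression and rng.random() < effect:
                mix = 0.9
                pb.expression[ds] = (mix * pa.expression[ds]
                                     + np.sqrt(1 - mix ** 2)
                                     * rng.normal(size=pa.expression[ds].size))

    # Uninformative reference tables: orthology and database flags fire at a
    # low background rate regardless of label.
    all_pairs = positives + negatives
    orthology = {}
    for org in ft.ORTHOLOGY_ORGANISMS:
        hits = rng.random(len(all_pairs)) < 0.05
        orthology[org] = {p for p, h in zip(all_pairs, hits) if h}
    databases = {}
    for db in ("MINT", "APID", "BIOGRID", "DB4"):
        hits = rng.random(len(all_pairs)) < 0.05
        databases[db] = {p for p, h in zip(all_pairs, hits) if h}

    # Pairwise E-values, log-uniform and label-independent by default.
    evalues = EvalueTable()
    for a, b in all_pairs:
        evalues.set(a, b, 10.0 ** rng.uniform(-5, 2))

    resources = FeatureResources(
        annotations=proteins, orthology=orthology, databases=databases,
        ddi=ddi, evalues=evalues, expression_datasets=expression_datasets,
    )

    # Labelled records, with label flips at the stated noise rate.
    records = []
    flips = rng.random(len(all_pairs)) < noise
    for (pair, flip, is_pos) in zip(all_pairs, flips,
                                    [True] * n_positive + [False] * n_negative):
        label = int(is_pos) ^ int(flip)
        methods = frozenset(_POSITIVE_METHODS if label == 1 else ())
        records.append(InteractionRecord(
            id_a=pair[0], id_b=pair[1], detection_methods=methods,
            taxon_host=9606, source_dbs=frozenset({"synthetic"}), label=label,
        ))

    manifest = {
        "seed": seed, "n_proteins": n_proteins, "n_positive": n_positive,
        "n_negative": n_negative, "noise": noise,
        "effect_sizes": effect_sizes,
        "informative_features": sorted(effect_sizes),
        "true_positives": ["|".join(p) for p in positives],
        "true_negatives": ["|".join(p) for p in negatives],
        "labels": {"|".join(r.pair): int(r.label) for r in records},
        "affinity_rule": dict(DEFAULT_AFFINITY_RULE),
    }
    return SyntheticWorld(
        proteins=proteins, true_positives=positives, true_negatives=negatives,
        records=records, resources=resources, effect_sizes=effect_sizes,
        noise=noise, seed=seed, affinity_rule=dict(DEFAULT_AFFINITY_RULE),
        manifest=manifest,
    )


def generate_affinity_table(
    world: SyntheticWorld,
    n_records: int = 60,
    sd: float = 1.0,
    seed: int = 0,
    kd_fraction: float = 0.5,
    include_decoys: bool = True,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Raw affinity measurement table with planted dG and curation decoys.

    dG is a linear combination of the planted pair features plus Gaussian
    noise; a ``kd_fraction`` of rows is emitted as Kd at a stated
    temperature (inverting dG = RT ln Kd), the rest directly as dG.
    Returns the raw table and the planted ground-truth dG per pair.
    """
    rng = np.random.default_rng(seed)
    rule = world.affinity_rule
    pool = world.true_positives
    if n_records > len(pool):
        raise ValueError("not enough planted positive pairs for the affinity table")
    idx = rng.choice(len(pool), size=n_records, replace=False)
    rows, truth = [], {}
    for i in sorted(idx):
        pair = pool[i]
        feats = _informative_pair_features(pair, world.resources)
        dg = rule["intercept"] + sum(
            w * feats[k] for k, w in rule.items() if k != "intercept"
        ) + rng.normal(0.0, sd)
        truth[pair] = dg
        as_kd = rng.random() < kd_fraction
        if as_kd:
            temp = float(rng.choice([298.0, 300.0, 310.0]))
            rows.append({"id_a": pair[0], "id_b": pair[1], "measure": "Kd",
                         "value": k_from_delta_g(dg, temp), "unit": "M",
                         "temperature_K": temp, "taxon": 9606,
                         "stoichiometry": "dimer"})
        else:
            rows.append({"id_a": pair[0], "id_b": pair[1], "measure": "dG",
                         "value": dg, "unit": "kJ/mol", "temperature_K": np.nan,
                         "taxon": 9606, "stoichiometry": "dimer"})
    if include_decoys and rows:
        first = rows[0]
        rows.append({**first})  # duplicate pair -> "duplicate"
        rows.append({"id_a": first["id_a"], "id_b": first["id_b"], "measure": "Kd",
                     "value": "1-10", "unit": "nM", "temperature_K": 298.0,
                     "taxon": 9606, "stoichiometry": "dimer"})  # "imprecise"
        rows.append({"id_a": first["id_a"], "id_b": first["id_b"], "measure": "IC50",
                     "value": 1e-6, "unit": "M", "temperature_K": 298.0,
                     "taxon": 9606, "stoichiometry": "dimer"})  # "unit"
        rows.append({"id_a": first["id_a"], "id_b": first["id_b"], "measure": "Kd",
                     "value": 1e-6, "unit": "M", "temperature_K": 298.0,
                     "taxon": 10090, "stoichiometry": "dimer"})  # "taxon"
        rows.append({"id_a": first["id_a"], "id_b": first["id_b"], "measure": "Kd",
                     "value": 1e-6, "unit": "M", "temperature_K": 298.0,
                     "taxon": 9606, "stoichiometry": "trimer"})  # "stoichiometry"
    return pd.DataFrame(rows), truth


def generate_tr_catalog(
    world: SyntheticWorld,
    n_tr: int = 10,
    classes: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Catalog of receptor accessions tagged with taste classes.

    One accession is tagged with two classes when at least two classes are
    requested (the heterodimer-subunit analogue). Row count equals the sum
    of the per-class counts.
    """
    if n_tr > len(world.proteins):
        raise ValueError("n_tr exceeds the number of world proteins")
    classes = classes or {"bitter": 4, "salty": 2, "sweet": 1, "umami": 2, "sour": 1}
    rng = np.random.default_rng(seed)
    accs = [str(a) for a in rng.choice(world.accessions, size=n_tr, replace=False)]
    assignments = [cls for cls, k in classes.items() for _ in range(k)]
    rows = [{"accession": accs[i % n_tr], "taste_class": cls}
            for i, cls in enumerate(assignments)]
    if len(classes) >= 2:
        # Heterodimer-subunit analogue: first accession carries two classes.
        second = next(c for c in assignments if c != assignments[0])
        if not any(r["accession"] == accs[0] and r["taste_class"] == second
                   for r in rows):
            for r in rows:
                if r["taste_class"] == second:
                    r["accession"] = accs[0]
                    break
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


# ---------------------------------------------------------------------------
# File writers (fixture files round-trip through the package readers)
# ---------------------------------------------------------------------------


def write_world(world: SyntheticWorld, outdir) -> dict[str, str]:
    """Write all fixture files; returns a name -> path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    pos = [r for r in world.records if r.label == 1]
    neg = [r for r in world.records if r.label == 0]
    mitab = pd.DataFrame({
        "uidA": [f"uniprotkb:{r.id_a}" for r in pos],
        "uidB": [f"uniprotkb:{r.id_b}" for r in pos],
        "method": ["|".join(f'psi-mi:"MI:0000"({m})' for m in sorted(r.detection_methods))
                   or "-" for r in pos],
        "Host_organism_taxid": [f"taxid:{r.taxon_host}(Homo sapiens)" for r in pos],
        "Checksum_Interaction": [r.rigid for r in pos],
        "sourcedb": ["synthetic" for _ in pos],
    })
    paths["mitab"] = str(out / "interactions.mitab.tsv")
    mitab.to_csv(paths["mitab"], sep="\t", index=False)

    paths["negatives"] = str(out / "negatives.tsv")
    pd.DataFrame({"id_a": [r.id_a for r in neg], "id_b": [r.id_b for r in neg]}
                 ).to_csv(paths["negatives"], sep="\t", index=False, header=False)

    paths["fasta"] = str(out / "proteome.fasta")
    with open(paths["fasta"], "w") as fh:
        for acc in world.accessions:
            fh.write(f">{acc}\n{world.proteins[acc].sequence}\n")

    go_rows = [(acc, asp, term)
               for acc in world.accessions
               for asp in ft.GO_ASPECTS
               for term in sorted(world.proteins[acc].go_terms.get(asp, ()))]
    paths["go"] = str(out / "go.tsv")
    pd.DataFrame(go_rows, columns=["accession", "aspect", "term"]
                 ).to_csv(paths["go"], sep="\t", index=False)

    pfam_rows = [(acc, d) for acc in world.accessions
                 for d in sorted(world.proteins[acc].pfam_domains)]
    paths["pfam"] = str(out / "pfam.tsv")
    pd.DataFrame(pfam_rows, columns=["accession", "domain"]
                 ).to_csv(paths["pfam"], sep="\t", index=False)

    paths["ddi"] = str(out / "ddi.tsv")
    pd.DataFrame(sorted(world.resources.ddi), columns=["domain_a", "domain_b"]
                 ).to_csv(paths["ddi"], sep="\t", index=False)

    loc_rows = [(acc, c) for acc in world.accessions
                for c in sorted(world.proteins[acc].localizations or ())]
    paths["loc"] = str(out / "localization.tsv")
    pd.DataFrame(loc_rows, columns=["accession", "compartment"]
                 ).to_csv(paths["loc"], sep="\t", index=False)

    expr_dir = out / "expression"
    expr_dir.mkdir(exist_ok=True)
    for ds in world.resources.expression_datasets:
        mat = pd.DataFrame(
            {acc: world.proteins[acc].expression[ds] for acc in world.accessions}
        ).T
        mat.columns = [f"sample_{i}" for i in range(mat.shape[1])]
        mat.to_csv(expr_dir / f"{ds}.tsv", sep="\t", index_label="accession")
    paths["expression_dir"] = str(expr_dir)

    ortho_rows = [(org, a, b) for org in sorted(world.resources.orthology)
                  for a, b in sorted(world.resources.orthology[org])]
    paths["orthology"] = str(out / "orthology.tsv")
    pd.DataFrame(ortho_rows, columns=["organism", "id_a", "id_b"]
                 ).to_csv(paths["orthology"], sep="\t", index=False)

    db_rows = [(db, a, b) for db in sorted(world.resources.databases)
               for a, b in sorted(world.resources.databases[db])]
    paths["databases"] = str(out / "database_pairs.tsv")
    pd.DataFrame(db_rows, columns=["database", "id_a", "id_b"]
                 ).to_csv(paths["databases"], sep="\t", index=False)

    ev_rows = [(a, b, e) for (a, b), e in sorted(world.resources.evalues.items())]
    paths["evalues"] = str(out / "evalues.tsv")
    pd.DataFrame(ev_rows, columns=["query", "subject", "evalue"]
                 ).to_csv(paths["evalues"], sep="\t", index=False)

    paths["manifest"] = str(out / "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(world.manifest, fh, indent=2, sort_keys=True)
    return paths


def load_resources(paths: dict[str, str],
                   expression_datasets: tuple[str, ...] = EXPRESSION_DATASETS
                   ) -> FeatureResources:
    """Rebuild :class:`FeatureResources` from written fixture files."""
    from Bio import SeqIO

    annotations: dict[str, ProteinAnnotation] = {}
    for rec in SeqIO.parse(paths["fasta"], "fasta"):
        annotations[rec.id] = ProteinAnnotation(accession=rec.id,
                                                sequence=str(rec.seq))
    go = pd.read_csv(paths["go"], sep="\t")
    for acc, grp in go.groupby("accession"):
        annotations[acc].go_terms = {
            asp: set(sub["term"]) for asp, sub in grp.groupby("aspect")
        }
    pfam = pd.read_csv(paths["pfam"], sep="\t")
    for acc, grp in pfam.groupby("accession"):
        annotations[acc].pfam_domains = set(grp["domain"])
    loc = pd.read_csv(paths["loc"], sep="\t")
    for acc, grp in loc.groupby("accession"):
        annotations[acc].localizations = set(grp["compartment"])
    expr_dir = Path(paths["expression_dir"])
    for ds_path in sorted(expr_dir.glob("*.tsv")):
        ds = ds_path.stem
        mat = pd.read_csv(ds_path, sep="\t", index_col="accession")
        for acc in mat.index:
            if acc in annotations:
                annotations[acc].expression[ds] = mat.loc[acc].to_numpy(dtype=float)
    ddi_df = pd.read_csv(paths["ddi"], sep="\t")
    ddi = {canonical_pair(a, b) for a, b in zip(ddi_df.domain_a, ddi_df.domain_b)}
    evalues = EvalueTable.from_tsv(paths["evalues"])
    orthology: dict[str, set] = {}
    if "orthology" in paths:
        odf = pd.read_csv(paths["orthology"], sep="\t")
        for org, grp in odf.groupby("organism"):
            orthology[org] = {canonical_pair(a, b)
                              for a, b in zip(grp.id_a, grp.id_b)}
    databases: dict[str, set] = {}
    if "databases" in paths:
        ddf = pd.read_csv(paths["databases"], sep="\t")
        for db, grp in ddf.groupby("database"):
            databases[db] = {canonical_pair(a, b)
                             for a, b in zip(grp.id_a, grp.id_b)}
    return FeatureResources(annotations=annotations, orthology=orthology,
                            databases=databases, ddi=ddi, evalues=evalues,
                            expression_datasets=expression_datasets)
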