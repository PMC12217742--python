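"""Interactome screening, ranking and export.

Enumerates every unordered pair containing at least one taste-receptor
accession, classifies each with the best Pareto-front model, predicts a
binding strength for the positive pairs with the regression ensemble, and
ranks positives by the mean of classifier probability and min-max scaled
affinity. Exports a Table-style library TSV, a SIF/edge-list network
above a probability threshold, and node attributes tagging receptor
classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import EndpointScaler
from .evaluation import ensemble_regress
from .interactions import canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class RankedInteraction:
    id_a: str
    id_b: str
    gene_a: str
    gene_b: str
    predicted_class: int
    probability: float
    predicted_dg_abs: float | None = None  # |dG| in kJ/mol; positives only
    scaled_affinity: float | None = None
    mean_score: float | None = None
    in_reference: int = 0

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    @property
    def pair_key(self) -> str:
        return f"{self.id_a}|{self.id_b}"


def enumerate_pairs(tr_ids: set[str], proteome_ids: set[str]) -> list[tuple[str, str]]:
    """All unordered pairs with >= 1 receptor id; no self-pairs, no dups."""
    if not tr_ids:
        raise ValueError("empty receptor id set")
    universe = set(proteome_ids) | set(tr_ids)
    pairs = {
        canonical_pair(t, other)
        for t in tr_ids for other in universe if other != t
    }
    return sorted(pairs)


def screen(
    pairs: list[tuple[str, str]],
    X: np.ndarray,
    classifier_front,
    regressor_front,
    scaler: EndpointScaler,
    gene_names: dict[str, str] | None = None,
    missing_mask: np.ndarray | None = None,
) -> list[RankedInteraction]:
    """Classify every pair and predict affinity for the positives.

    The classifier runs in best-model mode (class + probability for every
    pair); the regressor runs in ensemble mode on the positives only and
    its [0,1] endpoint predictions are inverted to kJ/mol through
    ``scaler``. Negative pairs carry no affinity. Positive pairs the
    regression ensemble cannot predict are flagged and excluded from
    ranking (logged).
    """
    X = np.asarray(X, dtype=float)
    if len(pairs) != X.shape[0]:
        raise ValueError("pairs and feature matrix disagree in length")
    gene_names = gene_names or {}
    best = classifier_front.best()
    prob = best.predict_proba(X)
    pred = (prob >= 0.5).astype(int)

    results = [
        RankedInteraction(
            id_a=a, id_b=b,
            gene_a=gene_names.get(a, a), gene_b=gene_names.get(b, b),
            predicted_class=int(c), probability=float(p),
        )
        for (a, b), c, p in zip(pairs, pred, prob)
    ]
    pos_idx = np.flatnonzero(pred == 1)
    if pos_idx.size:
        mm = missing_mask if missing_mask is None else np.asarray(missing_mask)[pos_idx]
        endpoint, unpredictable = ensemble_regress(
            regressor_front.members, X[pos_idx], missing_mask=mm
        )
        dg = scaler.inverse(endpoint)
        n_skip = int(unpredictable.sum())
        if n_skip:
            logger.info("screen: %d positive pair(s) unpredictable by the "
                        "regression ensemble; excluded from ranking", n_skip)
        for j, i in enumerate(pos_idx):
            if not unpredictable[j]:
                results[i].predicted_dg_abs = float(abs(dg[j]))
    return results


def rank_interactions(screened: list[RankedInteraction]) -> list[RankedInteraction]:
    """Rank positive pairs by mean of probability and scaled affinity.

    The binding-strength score is the min-max scaling of |dG| over the
    screened positive set (all equal -> 1.0 for every pair). Descending
    mean score; ties broken by probability, then pair key.
    """
    positives = [r for r in screened
                 if r.predicted_class == 1 and r.predicted_dg_abs is not None]
    if not positives:
        return []
    dgs = np.array([r.predicted_dg_abs for r in positives])
    span = float(np.ptp(dgs))
    for r, dg in zip(positives, dgs):
        r.scaled_affinity = float((dg - dgs.min()) / span) if span > 0 else 1.0
        r.mean_score = (r.probability + r.scaled_affinity) / 2.0
    return sorted(positives,
                  key=lambda r: (-r.mean_score, -r.probability, r.pair_key))


def export_library(
    ranked: list[RankedInteraction],
    top_n: int | None = None,
    reference_pairs: set[tuple[str, str]] | None = None,
    path=None,
) -> pd.DataFrame:
    """Ranked-library table: pair key, gene symbols, probability, |dG|,
    combined mean score and a reference-database presence flag."""
    reference_pairs = {canonical_pair(*p) for p in (reference_pairs or set())}
    rows = []
    for r in ranked[: top_n if top_n is not None else len(ranked)]:
        r.in_reference = int(r.pair in reference_pairs)
        rows.append({
            "TR interaction (UID)": f"{r.id_a}-{r.id_b}",
            "Gene1": r.gene_a,
            "Gene2": r.gene_b,
            "Probability score": round(r.probability, 4),
            "Aff predictions (kJ/mol)": round(r.predicted_dg_abs, 2),
            "Mean Prob-Scaled Aff": round(r.mean_score, 4),
            "iRefIndex check": r.in_reference,
        })
    df = pd.DataFrame(rows, columns=[
        "TR interaction (UID)", "Gene1", "Gene2", "Probability score",
        "Aff predictions (kJ/mol)", "Mean Prob-Scaled Aff", "iRefIndex check",
    ])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def export_network(
    ranked: list[RankedInteraction],
    probability_threshold: float = 0.55,
    tr_catalog: pd.DataFrame | None = None,
    outdir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list above a strict probability threshold plus node attributes.

    Edge weight is the combined mean score; node attributes carry the
    taste class(es) from the supplied receptor catalog ("non-TR" for all
    other proteins). When ``outdir`` is given, writes ``network.sif``,
    ``edges.tsv`` and ``nodes.tsv``.
    """
    edges = [r for r in ranked if r.probability > probability_threshold]
    edge_df = pd.DataFrame(
        [{"source": r.id_a, "target": r.id_b, "probability": r.probability,
          "weight": r.mean_score} for r in edges],
        columns=["source", "target", "probability", "weight"],
    )
    classes: dict[str, set[str]] = {}
    if tr_catalog is not None:
        for acc, grp in tr_catalog.groupby("accession"):
            classes[acc] = set(grp["taste_class"])
    nodes = sorted({n for r in edges for n in r.pair})
    node_df = pd.DataFrame(
        [{"node": n,
          "tr_class": "/".join(sorted(classes[n])) if n in classes else "non-TR"}
         for n in nodes],
        columns=["node", "tr_class"],
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "network.sif", "w") as fh:
            for r in edges:
                fh.write(f"{r.id_a}\tpp\t{r.id_b}\n")
        edge_df.to_csv(out / "edges.tsv", sep="\t", index=False)
        node_df.to_csv(out / "nodes.tsv", sep="\t", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump({"probability_threshold": probability_threshold,
                       "n_edges": len(edge_df), "n_nodes": len(node_df)}, fh,
                      indent=2)
    return edge_df, node_df
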