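"""Curation of binary protein-protein interaction datasets.

Reads iRefIndex-style PSI-MITAB tables, applies the curation cascade
(UniProt-only identifiers, RIGID/checksum deduplication, detection-method
and host-taxon filters), samples negatives at a fixed ratio, and removes
test pairs homologous to training pairs using precomputed E-values.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: UniProt accession pattern (the official 6/10-character format).
UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)


class MitabFormatError(ValueError):
    """A mandatory MITAB column is absent or unusable."""


class LabelConflictError(ValueError):
    """The same unordered pair carries both a positive and a negative label."""


class InsufficientPoolError(ValueError):
    """The negative pool is too small for the requested sampling ratio."""


def is_uniprot(accession: str) -> bool:
    return bool(UNIPROT_RE.match(accession))


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    """Order a pair lexicographically so unordered pairs compare equal."""
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


@dataclass(frozen=True)
class InteractionRecord:
    """One unordered protein pair with provenance."""

    id_a: str
    id_b: str
    rigid: str = ""
    detection_methods: frozenset[str] = frozenset()
    taxon_host: int | None = None
    source_dbs: frozenset[str] = frozenset()
    label: int | None = None  # 1 positive, 0 negative, None unlabelled

    def __post_init__(self):
        a, b = canonical_pair(self.id_a, self.id_b)
        object.__setattr__(self, "id_a", a)
        object.__setattr__(self, "id_b", b)
        if not self.rigid:
            # RIGID semantics is "same set of proteins": fall back to the
            # canonical unordered pair key when the column is absent.
            object.__setattr__(self, "rigid", f"{a}|{b}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    @property
    def uniprot_valid(self) -> bool:
        return is_uniprot(self.id_a) and is_uniprot(self.id_b)


@dataclass
class DatasetSplit:
    train: list[InteractionRecord]
    test: list[InteractionRecord]
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MitabDialect:
    """Column map for a MITAB-style TSV (iRefIndex naming by default)."""

    id_a: str = "uidA"
    id_b: str = "uidB"
    rigid: str = "Checksum_Interaction"
    method: str = "method"
    taxon_host: str = "Host_organism_taxid"
    source_db: str = "sourcedb"

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (self.id_a, self.id_b, self.method, self.taxon_host)


_PREFIX_RE = re.compile(r"^[a-zA-Z_\-]+:")
_PAREN_RE = re.compile(r"\(([^)]*)\)")


def _strip_prefix(value: str) -> str:
    """``uniprotkb:P12345`` -> ``P12345``; plain values pass through."""
    return _PREFIX_RE.sub("", value.strip().strip('"'))


def _parse_methods(cell: str) -> frozenset[str]:
    """Extract method names from ``psi-mi:"MI:0018"(two hybrid)|...``."""
    if not cell or cell == "-":
        return frozenset()
    out = set()
    for part in str(cell).split("|"):
        m = _PAREN_RE.search(part)
        out.add(m.group(1).strip() if m else _strip_prefix(part).strip('"'))
    return frozenset(x for x in out if x)


def _parse_taxon(cell) -> int | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell)
    m = re.search(r"(-?\d+)", s)
    return int(m.group(1)) if m else None


def read_mitab(path, dialect: MitabDialect | None = None) -> list[InteractionRecord]:
    """Read an interaction table into records.

    One record is produced per data row; identifiers are canonicalized to the
    unordered form. Rows with non-UniProt identifiers are kept (flagged via
    :attr:`InteractionRecord.uniprot_valid`) and reported, so that
    :func:`filter_uniprot_only` can remove them explicitly.
    """
    dialect = dialect or MitabDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns.size and df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    for col in dialect.mandatory:
        if col not in df.columns:
            raise MitabFormatError(f"missing mandatory MITAB column: {col!r}")
    has_rigid = dialect.rigid in df.columns
    has_db = dialect.source_db in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        rec = InteractionRecord(
            id_a=_strip_prefix(row[dialect.id_a]),
            id_b=_strip_prefix(row[dialect.id_b]),
            rigid=row[dialect.rigid].strip() if has_rigid else "",
            detection_methods=_parse_methods(row[dialect.method]),
            taxon_host=_parse_taxon(row[dialect.taxon_host]),
            source_dbs=_parse_methods(row[dialect.source_db]) if has_db else frozenset(),
        )
        if not rec.uniprot_valid:
            logger.warning("row %d: non-UniProt identifier in pair %s", i, rec.pair)
        records.append(rec)
    return records


def filter_uniprot_only(records: list[InteractionRecord]) -> list[InteractionRecord]:
    """Keep records where both proteins carry a valid UniProt accession."""
    return [r for r in records if r.uniprot_valid]


def dedup_by_rigid(records: list[InteractionRecord]) -> list[InteractionRecord]:
    """Keep the first occurrence per redundancy-group key (idempotent)."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.rigid not in seen:
            seen.add(r.rigid)
            out.append(r)
    return out


def filter_by_methods(
    records: list[InteractionRecord], allowed: set[str], mode: str = "include"
) -> list[InteractionRecord]:
    """Filter by detection method.

    ``include`` keeps records with at least one method in ``allowed`` (the
    training-set rule, e.g. {two hybrid, tandem affinity purification});
    ``exclude`` keeps records with no method in ``allowed`` (the test-set
    rule: every other detection method).
    """
    if not allowed:
        raise ValueError("allowed method set must be non-empty")
    if mode not in ("include", "exclude"):
        raise ValueError(f"mode must be 'include' or 'exclude', got {mode!r}")
    if mode == "include":
        return [r for r in records if r.detection_methods & allowed]
    return [r for r in records if not (r.detection_methods & allowed)]


def filter_by_taxon(records: list[InteractionRecord], taxon: int) -> list[InteractionRecord]:
    """Keep records whose host organism matches ``taxon`` (9606 for human)."""
    return [r for r in records if r.taxon_host == taxon]


def sample_negatives(
    positives: list[InteractionRecord],
    negative_pool: list[InteractionRecord],
    ratio: float,
    seed: int,
) -> list[InteractionRecord]:
    """Sample ``round(ratio * |positives|)`` negatives without replacement."""
    import numpy as np

    n_needed = round(ratio * len(positives))
    if n_needed > len(negative_pool):
        raise InsufficientPoolError(
            f"need {n_needed} negatives but pool has only {len(negative_pool)} "
            f"(shortfall {n_needed - len(negative_pool)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negative_pool), size=n_needed, replace=False)
    return [replace(negative_pool[i], label=0) for i in sorted(idx)]


class EvalueTable:
    """Symmetric lookup of pairwise alignment E-values."""

    def __init__(self, entries: dict[tuple[str, str], float] | None = None):
        self._e: dict[tuple[str, str], float] = {}
        for (a, b), v in (entries or {}).items():
            self._e[canonical_pair(a, b)] = float(v)

    def set(self, a: str, b: str, evalue: float) -> None:
        self._e[canonical_pair(a, b)] = float(evalue)

    def get(self, a: str, b: str) -> float | None:
        return self._e.get(canonical_pair(a, b))

    def __len__(self) -> int:
        return len(self._e)

    def items(self):
        return self._e.items()

    @classmethod
    def from_tsv(cls, path, query_col="query", subject_col="subject", evalue_col="evalue"):
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for q, s, e in zip(df[query_col], df[subject_col], df[evalue_col]):
            table.set(str(q), str(s), float(e))
        return table


def exclude_similar_pairs(
    test: list[InteractionRecord],
    train: list[InteractionRecord],
    evalues: EvalueTable,
    threshold: float = 0.05,
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Remove test pairs homologous to any training pair.

    A test pair (a, b) is removed iff some train pair (c, d) satisfies
    E(a,c) < t and E(b,d) < t, or E(a,d) < t and E(b,c) < t — i.e. *both*
    proteins of the test pair are similar to the two proteins of one train
    pair. Missing E-values are treated as not-similar (conservative
    retention) and counted in the log.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    train_pairs = [r.pair for r in train]
    missing = 0

    def similar(x: str, y: str) -> bool:
        nonlocal missing
        e = evalues.get(x, y)
        if e is None:
            missing += 1
            return False
        return e < threshold

    kept, removed = [], []
    for rec in test:
        a, b = rec.pair
        hit = any(
            (similar(a, c) and similar(b, d)) or (similar(a, d) and similar(b, c))
            for c, d in train_pairs
        )
        (removed if hit else kept).append(rec)
    if missing:
        logger.info("exclude_similar_pairs: %d missing E-value lookups treated as not-similar", missing)
    return kept, removed


def split_train_test(records: list, train_fraction: float, seed: int) -> DatasetSplit:
    """Random disjoint split with ``|train| = floor(fraction * n)``."""
    import numpy as np

    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = math.floor(train_fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [records[i] for i in perm[:n_train]]
    test = [records[i] for i in perm[n_train:]]
    return DatasetSplit(
        train=train,
        test=test,
        provenance={"n": n, "train_fraction": train_fraction, "seed": seed,
                    "n_train": n_train, "n_test": n - n_train},
    )


def assemble_dataset(
    positives: list[InteractionRecord], negatives: list[InteractionRecord]
) -> list[InteractionRecord]:
    """Combine labelled records, rejecting pairs labelled both ways."""
    pos = [replace(r, label=1) for r in positives]
    neg = [replace(r, label=0) for r in negatives]
    pos_keys = {r.pair for r in pos}
    conflicts = [r.pair for r in neg if r.pair in pos_keys]
    if conflicts:
        raise LabelConflictError(
            f"{len(conflicts)} pair(s) labelled both positive and negative, e.g. {conflicts[0]}"
        )
    return pos + neg


def read_negative_list(path) -> list[InteractionRecord]:
    """Read a two-column accession list of non-interacting pairs."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id_a", "id_b"], dtype=str, comment="#")
    return [InteractionRecord(id_a=a, id_b=b, label=0) for a, b in zip(df.id_a, df.id_b)]


def write_dataset(records: list[InteractionRecord], path, provenance: dict | None = None) -> None:
    """Write id_a/id_b/label TSV plus a JSON provenance sidecar."""
    df = pd.DataFrame(
        {"id_a": [r.id_a for r in records],
         "id_b": [r.id_b for r in records],
         "label": [r.label for r in records]}
    )
    df.to_csv(path, sep="\t", index=False)
    if provenance is not None:
        with open(str(path) + ".provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
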