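"""Data model and on-disk formats for benchmark artifacts.

The toolkit revolves around four objects:

* :class:`AssociationStandard` — the curated drug–indication "gold standard"
  mapping against which rankings are scored;
* :class:`SignatureMatrix` — the drugs × proteins interaction-score matrix
  that characterizes each drug's predicted proteomic behavior;
* :class:`NeighborRanking` — one drug's ordered list of all other drugs by
  signature similarity;
* :class:`RelevanceVector` — binary (or graded) relevance labels along a
  ranking, the common input to every ranking/classification metric;
* :class:`MetricReport` — per-indication and aggregate metric values, with
  optional paired null-control values.

All delimited files are tab-separated UTF-8 with ``#``-prefixed comment
lines.  Identifiers are opaque case-sensitive strings; indication IDs in the
shipped fixtures follow the MeSH ``D######`` pattern but are not validated
against any vocabulary.  Ranks are 1-based throughout the toolkit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationStandard",
    "SignatureMatrix",
    "NeighborRanking",
    "RelevanceVector",
    "AggregateStats",
    "MetricReport",
    "read_association_standard",
    "write_association_standard",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_metric_report",
    "write_metric_report",
]


class ParseError(ValueError):
    """A delimited input file violated its dialect."""


@dataclass(frozen=True)
class AssociationStandard:
    """A deduplicated set of (drug, indication) associations.

    Drugs with zero associations are permitted — they act as inactives for
    every indication.  Every listed indication has at least one associated
    drug.
    """

    associations: frozenset[tuple[str, str]]
    drugs: tuple[str, ...]
    indications: tuple[str, ...]

    def __post_init__(self) -> None:
        drug_set = set(self.drugs)
        ind_set = set(self.indications)
        if len(drug_set) != len(self.drugs):
            raise ValueError("duplicate drug ids")
        if len(ind_set) != len(self.indications):
            raise ValueError("duplicate indication ids")
        covered = set()
        for d, i in self.associations:
            if d not in drug_set:
                raise ValueError(f"association references unlisted drug {d!r}")
            if i not in ind_set:
                raise ValueError(f"association references unlisted indication {i!r}")
            covered.add(i)
        missing = ind_set - covered
        if missing:
            raise ValueError(
                f"indications with no associated drug: {sorted(missing)[:5]}"
            )

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        drugs: Sequence[str] | None = None,
    ) -> "AssociationStandard":
        """Build a standard from raw pairs, deduplicating silently.

        ``drugs`` may list extra drugs that carry no association.
        """
        assoc = frozenset((str(d), str(i)) for d, i in pairs)
        seen_drugs = {d for d, _ in assoc}
        if drugs is None:
            all_drugs = tuple(sorted(seen_drugs))
        else:
            extra = seen_drugs - set(drugs)
            if extra:
                raise ValueError(f"pairs reference drugs not listed: {sorted(extra)[:5]}")
            all_drugs = tuple(drugs)
        inds = tuple(sorted({i for _, i in assoc}))
        return cls(associations=assoc, drugs=all_drugs, indications=inds)

    @property
    def n_associations(self) -> int:
        return len(self.associations)

    def indication_drugs(self, indication_id: str) -> frozenset[str]:
        """The set of drugs associated with one indication."""
        return frozenset(d for d, i in self.associations if i == indication_id)

    def indication_sizes(self) -> dict[str, int]:
        sizes = {i: 0 for i in self.indications}
        for _, i in self.associations:
            sizes[i] += 1
        return sizes

    def drug_indications(self, drug_id: str) -> frozenset[str]:
        return frozenset(i for d, i in self.associations if d == drug_id)

    def by_indication(self) -> dict[str, frozenset[str]]:
        """Map every indication to its drug set (single pass)."""
        out: dict[str, set[str]] = {i: set() for i in self.indications}
        for d, i in self.associations:
            out[i].add(d)
        return {k: frozenset(v) for k, v in out.items()}


@dataclass(frozen=True)
class SignatureMatrix:
    """Dense drugs × proteins interaction-score matrix.

    Scores are dimensionless reals; every entry must be finite.
    """

    drug_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        if scores.shape != (len(self.drug_ids), len(self.protein_ids)):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.protein_ids)} proteins"
            )
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")
        if not np.isfinite(scores).all():
            bad = [self.drug_ids[r] for r in np.unique(np.nonzero(~np.isfinite(scores))[0])]
            raise ValueError(f"non-finite scores for drugs {bad[:5]}")

    def row(self, drug_id: str) -> np.ndarray:
        return self.scores[self.drug_ids.index(drug_id)]


@dataclass(frozen=True)
class NeighborRanking:
    """All non-query drugs ordered by ascending distance to the query.

    Position 1 (index 0) is the most similar drug.  The query itself is
    excluded, so the list has N − 1 entries for an N-drug library.
    """

    query_drug: str
    ranked_drugs: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        dist = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", dist)
        if self.query_drug in self.ranked_drugs:
            raise ValueError("query drug must not appear in its own ranking")
        if len(self.ranked_drugs) != dist.shape[0]:
            raise ValueError("ranked_drugs and distances lengths differ")
        if dist.size and ((dist < 0).any() or (np.diff(dist) < 0).any()):
            raise ValueError("distances must be non-negative and non-decreasing")

    def __len__(self) -> int:
        return len(self.ranked_drugs)

    def rank_of(self, drug_id: str) -> int:
        """1-based rank of ``drug_id`` in the list."""
        return self.ranked_drugs.index(drug_id) + 1


@dataclass(frozen=True)
class RelevanceVector:
    """Relevance grades along a ranking; grade 0 marks an inactive.

    ``rel[i]`` is the grade of the item at 1-based rank ``i + 1``.  Binary
    {0, 1} grades are the default; integer grades > 1 express graded
    relevance.
    """

    rel: tuple[int, ...]

    def __post_init__(self) -> None:
        rel = tuple(int(r) for r in self.rel)
        if any(r < 0 for r in rel):
            raise ValueError("relevance grades must be non-negative")
        object.__setattr__(self, "rel", rel)

    @property
    def N(self) -> int:
        return len(self.rel)

    @property
    def n_actives(self) -> int:
        return sum(1 for r in self.rel if r > 0)

    @property
    def active_ranks(self) -> tuple[int, ...]:
        """1-based ranks of the actives, ascending."""
        return tuple(i + 1 for i, r in enumerate(self.rel) if r > 0)


@dataclass(frozen=True)
class AggregateStats:
    """Mean, median and interquartile range of a metric across indications."""

    mean: float
    median: float
    q1: float
    q3: float

    @classmethod
    def of(cls, values: Sequence[float]) -> "AggregateStats":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError("cannot aggregate zero values")
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        return cls(mean=float(arr.mean()), median=float(med), q1=float(q1), q3=float(q3))


# cutoff key for metrics evaluated on the full list rather than at a rank cutoff
FULL_LIST = "all"

PerIndication = dict[str, dict[str, dict[object, float]]]
Aggregate = dict[str, dict[object, AggregateStats]]


@dataclass
class MetricReport:
    """Per-indication and aggregate metric values, with optional null control.

    ``per_indication[ind][metric][cutoff]`` is a scalar; cutoffs are 1-based
    integer ranks or the string ``"all"`` for whole-list metrics.  The
    aggregate mean for a metric/cutoff is always the unweighted arithmetic
    mean of the per-indication values.  ``per_pair`` optionally carries the
    alternative aggregation where every drug–indication pair counts equally.
    """

    per_indication: PerIndication = field(default_factory=dict)
    aggregate: Aggregate = field(default_factory=dict)
    per_pair: Aggregate = field(default_factory=dict)
    null_control: "MetricReport | None" = None

    @classmethod
    def from_per_indication(
        cls,
        per_indication: PerIndication,
        per_pair: Aggregate | None = None,
    ) -> "MetricReport":
        agg: Aggregate = {}
        for ind_values in per_indication.values():
            for metric, by_cutoff in ind_values.items():
                for cutoff in by_cutoff:
                    agg.setdefault(metric, {}).setdefault(cutoff, None)
        for metric, by_cutoff in agg.items():
            for cutoff in by_cutoff:
                vals = [
                    per_indication[ind][metric][cutoff]
                    for ind in per_indication
                    if metric in per_indication[ind]
                    and cutoff in per_indication[ind][metric]
                ]
                by_cutoff[cutoff] = AggregateStats.of(vals)
        return cls(per_indication=per_indication, aggregate=agg,
                   per_pair=per_pair or {})

    def validate(self, atol: float = 1e-9) -> None:
        """Check the aggregate-mean bookkeeping invariant."""
        recomputed = MetricReport.from_per_indication(self.per_indication)
        for metric, by_cutoff in self.aggregate.items():
            for cutoff, stats in by_cutoff.items():
                expect = recomputed.aggregate[metric][cutoff]
                if not math.isclose(stats.mean, expect.mean, abs_tol=atol):
                    raise ValueError(
                        f"aggregate mean for {metric}@{cutoff} inconsistent with "
                        f"per-indication values"
                    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_association_standard(path) -> AssociationStandard:
    """Read a two-column ``drug_id<TAB>indication_id`` mapping file.

    Duplicate pairs are dropped (the count is logged).  Lines with fewer than
    two tab-separated fields raise :class:`ParseError` naming the line.
    """
    pairs: list[tuple[str, str]] = []
    orphans: list[str] = []
    any_line = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                # zero-association drugs survive round trips as tagged comments
                fields = line.lstrip("# ").split("\t")
                if fields[0] == "orphan-drug" and len(fields) == 2:
                    orphans.append(fields[1])
                continue
            any_line = True
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected 'drug<TAB>indication', got {line!r}"
                )
            pairs.append((fields[0], fields[1]))
    if not any_line:
        raise ParseError(f"{path}: empty association file")
    unique = set(pairs)
    dropped = len(pairs) - len(unique)
    if dropped:
        logger.info("read_association_standard: dropped %d duplicate pairs", dropped)
    drugs = tuple(sorted({d for d, _ in unique} | set(orphans)))
    return AssociationStandard.from_pairs(unique, drugs=drugs)


def write_association_standard(standard: AssociationStandard, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_id\tindication_id\n")
        for d, i in sorted(standard.associations):
            fh.write(f"{d}\t{i}\n")
        # drugs with zero associations are preserved as comment metadata
        orphans = sorted(set(standard.drugs) - {d for d, _ in standard.associations})
        for d in orphans:
            fh.write(f"# orphan-drug\t{d}\n")


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a signature TSV: header ``drug_id<TAB>prot1...``, one row per drug."""
    rows = list(_data_lines(path))
    if not rows:
        raise ParseError(f"{path}: empty signature file")
    _, header = rows[0]
    cols = header.split("\t")
    if len(cols) < 2:
        raise ParseError(f"{path}: header must list at least one protein column")
    protein_ids = tuple(cols[1:])
    drug_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(protein_ids)), dtype=float)
    for r, (lineno, line) in enumerate(rows[1:]):
        fields = line.split("\t")
        drug = fields[0]
        if len(fields) != len(protein_ids) + 1:
            raise ParseError(
                f"{path}:{lineno}: drug {drug!r} has {len(fields) - 1} scores, "
                f"expected {len(protein_ids)}"
            )
        try:
            data[r] = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score for drug {drug!r}: {exc}")
        drug_ids.append(drug)
    return SignatureMatrix(tuple(drug_ids), protein_ids, data)


def write_signature_matrix(matrix: SignatureMatrix, path, precision: int = 10) -> None:
    fmt = f"%.{precision}g"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\t" + "\t".join(matrix.protein_ids) + "\n")
        for drug, row in zip(matrix.drug_ids, matrix.scores):
            fh.write(drug + "\t" + "\t".join(fmt % x for x in row) + "\n")


def _cutoff_key(c: object) -> str:
    return str(c)


def _parse_cutoff(s: str) -> object:
    return int(s) if s.isdigit() else s


def _agg_to_json(agg: Aggregate) -> dict:
    return {
        m: {_cutoff_key(c): vars(st) for c, st in by.items()}
        for m, by in agg.items()
    }


def _agg_from_json(obj: Mapping) -> Aggregate:
    return {
        m: {_parse_cutoff(c): AggregateStats(**st) for c, st in by.items()}
        for m, by in obj.items()
    }


def report_to_dict(report: MetricReport) -> dict:
    d = {
        "per_indication": {
            ind: {m: {_cutoff_key(c): v for c, v in by.items()}
                  for m, by in metrics.items()}
            for ind, metrics in report.per_indication.items()
        },
        "aggregate": _agg_to_json(report.aggregate),
        "per_pair": _agg_to_json(report.per_pair),
    }
    if report.null_control is not None:
        d["null_control"] = report_to_dict(report.null_control)
    return d


def report_from_dict(obj: Mapping) -> MetricReport:
    per_ind = {
        ind: {m: {_parse_cutoff(c): float(v) for c, v in by.items()}
              for m, by in metrics.items()}
        for ind, metrics in obj.get("per_indication", {}).items()
    }
    null = obj.get("null_control")
    return MetricReport(
        per_indication=per_ind,
        aggregate=_agg_from_json(obj.get("aggregate", {})),
        per_pair=_agg_from_json(obj.get("per_pair", {})),
        null_control=report_from_dict(null) if null is not None else None,
    )


def write_metric_report(report: MetricReport, path, format: str = "json") -> None:
    """Serialize a report as JSON (lossless) or long-format TSV (values only)."""
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report_to_dict(report), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("indication_id\tmetric\tcutoff\tvalue\n")
            for ind in sorted(report.per_indication):
                for m in sorted(report.per_indication[ind]):
                    for c, v in sorted(
                        report.per_indication[ind][m].items(), key=lambda kv: str(kv[0])
                    ):
                        fh.write(f"{ind}\t{m}\t{c}\t{v:.10g}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_metric_report(path) -> MetricReport:
    with open(path, "r", encoding="utf-8") as fh:
        return report_from_dict(json.load(fh))
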