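"""Readers and writers for the package's text formats.

* expression matrix: TSV, first column ``gene_id`` (genes-as-rows, the
  usual microarray export) or samples-as-rows; orientation is
  auto-detected against the labels file and can be forced.
* labels: two-column TSV ``sample_id<TAB>class``.
* rule sets: one rule per line,
  ``Exp(g) in [lo,hi] AND ... -> class``, final line ``DEFAULT -> class``;
  bounds are written with ``repr`` precision so round trips are exact.
* ensembles: structured JSON (ordered rules, predicates, classes, seeds).
* fold plans: three-column TSV ``sample_id<TAB>fold<TAB>scheme``.
* rankings: three-column TSV ``rank<TAB>gene_id<TAB>score``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DataFormatError, ExpressionDataset, FoldPlan
from .rules import DecisionList, IntervalPredicate, Rule, RuleEnsemble
from .selection import FeatureRanking


def read_labels(labels_path: str | Path) -> dict[str, str]:
    df = pd.read_csv(labels_path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise DataFormatError(f"labels file must have 2 columns, got {df.shape[1]}")
    if df.iloc[:, 0].duplicated().any():
        dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()].iloc[0]
        raise DataFormatError(f"duplicate sample identifier in labels: {dup!r}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression_matrix(
    matrix_path: str | Path,
    labels_path: str | Path,
    orientation: str = "auto",
) -> ExpressionDataset:
    """Read a TSV expression matrix plus a sample->class label table.

    ``orientation`` is ``"genes-rows"``, ``"samples-rows"`` or ``"auto"``
    (detected by intersecting the header/first column with the labelled
    sample identifiers).  The returned dataset is always samples x genes.
    """
    labels_map = read_labels(labels_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        raise DataFormatError(
            f"duplicate identifier in first column: {df.index[df.index.duplicated()][0]!r}"
        )
    if pd.Index(df.columns).duplicated().any():
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise DataFormatError(f"duplicate identifier in header: {dup!r}")
    if orientation == "auto":
        cols_hit = len(set(df.columns) & labels_map.keys())
        rows_hit = len(set(df.index) & labels_map.keys())
        orientation = "genes-rows" if cols_hit >= rows_hit else "samples-rows"
    if orientation == "genes-rows":
        df = df.T  # -> samples x genes
    elif orientation != "samples-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise DataFormatError(
                        f"non-numeric cell at sample {df.index[i]!r}, "
                        f"gene {df.columns[j]!r}: {cell!r}"
                    ) from None
        raise
    samples = list(df.index)
    missing = [s for s in samples if s not in labels_map]
    if missing:
        raise DataFormatError(f"sample(s) without label: {missing[:5]}")
    labels = [labels_map[s] for s in samples]
    if len(set(labels)) > 2:
        raise DataFormatError(f"more than two classes: {sorted(set(labels))}")
    return ExpressionDataset(genes=list(df.columns), samples=samples,
                             values=values, labels=labels)


def write_expression_matrix(dataset: ExpressionDataset, matrix_path: str | Path,
                            labels_path: str | Path) -> None:
    """Write genes-as-rows TSV (first column ``gene_id``) plus a labels TSV."""
    df = pd.DataFrame(dataset.values.T, index=dataset.genes, columns=dataset.samples)
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t")  # str(float) is shortest-repr: exact round trip
    with open(labels_path, "w") as fh:
        for s, c in zip(dataset.samples, dataset.labels):
            fh.write(f"{s}\t{c}\n")


# ---------------------------------------------------------------------------
# rule sets

_PRED_RE = re.compile(r"^Exp\((?P<gene>[^)]+)\) in \[(?P<lo>[^,]+),(?P<hi>[^\]]+)\]$")


def _format_rule(rule: Rule) -> str:
    if rule.is_default:
        return f"DEFAULT -> {rule.predicted_class}"
    parts = [f"Exp({p.gene}) in [{p.lo!r},{p.hi!r}]" for p in rule.predicates]
    return " AND ".join(parts) + f" -> {rule.predicted_class}"


def _parse_rule(line: str, lineno: int) -> Rule:
    body, sep, cls = line.rpartition(" -> ")
    if not sep or not cls:
        raise DataFormatError(f"line {lineno}: missing '-> class' in {line!r}")
    if body == "DEFAULT":
        return Rule((), cls)
    preds = []
    for chunk in body.split(" AND "):
        m = _PRED_RE.match(chunk.strip())
        if not m:
            raise DataFormatError(f"line {lineno}: malformed predicate {chunk!r}")
        preds.append(IntervalPredicate(m["gene"], float(m["lo"]), float(m["hi"])))
    return Rule(tuple(preds), cls)


def write_ruleset(dl: DecisionList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rule in dl.rules:
            fh.write(_format_rule(rule) + "\n")


def read_ruleset(path: str | Path) -> DecisionList:
    rules = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if line and not line.startswith("#"):
                rules.append(_parse_rule(line, i))
    if not rules or not rules[-1].is_default:
        raise DataFormatError("rule set must end with a 'DEFAULT -> class' line")
    return DecisionList(rules)


def _rule_to_json(rule: Rule) -> dict:
    return {
        "predicates": [{"gene": p.gene, "lo": p.lo, "hi": p.hi} for p in rule.predicates],
        "class": rule.predicted_class,
    }


def _rule_from_json(d: dict) -> Rule:
    preds = tuple(IntervalPredicate(p["gene"], p["lo"], p["hi"]) for p in d["predicates"])
    return Rule(preds, d["class"])


def write_ensemble(ensemble: RuleEnsemble, path: str | Path) -> None:
    doc = {
        "class_prevalence": ensemble.class_prevalence,
        "members": [
            {
                "seed": dl.seed,
                "params": dl.params,
                "rules": [_rule_to_json(r) for r in dl.rules],
            }
            for dl in ensemble.members
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_ensemble(path: str | Path) -> RuleEnsemble:
    doc = json.loads(Path(path).read_text())
    members = [
        DecisionList([_rule_from_json(r) for r in m["rules"]],
                     seed=m.get("seed"), params=m.get("params") or {})
        for m in doc["members"]
    ]
    return RuleEnsemble(members=members, class_prevalence=doc["class_prevalence"])


# ---------------------------------------------------------------------------
# fold plans and rankings


def write_fold_plan(plan: FoldPlan, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, f in zip(plan.samples, plan.assignments):
            fh.write(f"{s}\t{int(f)}\t{plan.scheme}\n")


def read_fold_plan(path: str | Path, seed: int = 0) -> FoldPlan:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["sample_id", "fold", "scheme"], dtype=str)
    return FoldPlan(
        scheme=df["scheme"].iloc[0],
        assignments=df["fold"].astype(int).to_numpy(),
        seed=seed,
        samples=list(df["sample_id"]),
    )


def write_ranking(ranking: FeatureRanking, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tscore\n")
        for i, (g, s) in enumerate(zip(ranking.genes, ranking.scores), start=1):
            fh.write(f"{i}\t{g}\t{float(s)!r}\n")


def read_ranking(path: str | Path, method: str = "unknown") -> FeatureRanking:
    df = pd.read_csv(path, sep="\t")
    return FeatureRanking(genes=list(df["gene_id"].astype(str)),
                          scores=df["score"].to_numpy(dtype=float), method=method)
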