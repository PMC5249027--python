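"""Readers and writers for the CSV/JSON formats shared by all stages.

All files are UTF-8; CSVs are comma-separated with a header row; JSON
numbers are written unformatted at full precision so that write -> read
round-trips reproduce the in-memory objects exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .agreement import AgreementReport, ItemClassification
from .priors import PriorSpec
from .votes import CATEGORIES, VoteMatrix


def read_votes_csv(path) -> VoteMatrix:
    """Read ``item_id,SAT,FoS,BSI,SUP,SOC,MOB,OUT,REJECT`` vote counts.

    ``n_raters`` is taken from the (constant) row sums.
    """
    df = pd.read_csv(path)
    if "item_id" not in df.columns:
        raise ValueError("votes CSV must have an item_id column")
    df = df.set_index("item_id")
    missing = [c for c in CATEGORIES if c not in df.columns]
    if missing:
        raise ValueError(f"votes CSV lacks category columns {missing}")
    df = df[list(CATEGORIES)]
    sums = df.sum(axis=1)
    if sums.nunique() != 1:
        raise ValueError("rows do not all sum to the same rater count")
    return VoteMatrix(df, int(sums.iloc[0]))


def write_votes_csv(votes: VoteMatrix, path) -> None:
    votes.counts.rename_axis("item_id").to_csv(path)


def write_classification_csv(c: ItemClassification, path) -> None:
    """``item_id,status,factor_or_reason`` with assigned items first."""
    rows = [{"item_id": i, "status": "assigned", "factor_or_reason": f}
            for i, f in sorted(c.assignments.items())]
    rows += [{"item_id": i, "status": "excluded", "factor_or_reason": r}
             for i, r in sorted(c.exclusions.items())]
    pd.DataFrame(rows, columns=["item_id", "status", "factor_or_reason"]) \
        .to_csv(path, index=False)


def read_classification_csv(path) -> ItemClassification:
    df = pd.read_csv(path)
    assignments, exclusions = {}, {}
    for r in df.itertuples():
        if r.status == "assigned":
            assignments[int(r.item_id)] = r.factor_or_reason
        elif r.status == "excluded":
            exclusions[int(r.item_id)] = r.factor_or_reason
        else:
            raise ValueError(f"unknown status {r.status!r}")
    return ItemClassification(assignments, exclusions)


def write_agreement_json(report: AgreementReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def priors_to_json(priors: list[PriorSpec], path) -> None:
    """Deterministically ordered JSON array of prior specifications."""
    payload = [{
        "name": p.name, "role": p.role, "item": p.item_id, "factor": p.factor,
        "family": p.family, "params": list(p.params),
        "informed": p.informed, "replaced": p.replaced,
    } for p in priors]
    Path(path).write_text(json.dumps(payload, indent=2))


def priors_from_json(path) -> list[PriorSpec]:
    payload = json.loads(Path(path).read_text())
    return [PriorSpec(
        role=d["role"], family=d["family"], params=tuple(d["params"]),
        item_id=d["item"], factor=d["factor"],
        informed=d["informed"], replaced=d["replaced"],
    ) for d in payload]


def read_responses_csv(path) -> pd.DataFrame:
    """``respondent_id,item_1,...`` Likert table; empty cell = omitted."""
    df = pd.read_csv(path)
    if "respondent_id" in df.columns:
        df = df.set_index("respondent_id")
    return df.astype(float)


def write_responses_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "respondent_id"
    out.to_csv(path, float_format="%g")


def write_posterior(samples, outdir, provenance: dict | None = None) -> None:
    """Draws as long CSV plus a JSON summary with diagnostics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples.draws_long().to_csv(outdir / "draws.csv", index=False)
    summary = samples.summary()
    payload = {
        "meta": {k: v for k, v in samples.meta.items()
                 if not isinstance(v, dict)},
        "parameters": json.loads(summary.reset_index()
                                 .to_json(orient="records")),
    }
    if provenance:
        payload["provenance"] = provenance
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2))
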