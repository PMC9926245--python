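"""HDAC repression- and recruitment-model staged set-intersection classifiers.

Two mechanistic models explain how losing a transcription factor changes
histone acetylation and expression at its targets:

* **repression model** — the TF keeps HDACs off chromatin.  Losing the TF
  lets HDACs act, so acetylation and expression drop, and HDAC inhibition
  (TSA) rescues expression.  Candidates are genes down in KD with loss of
  H3K27ac; confirmation requires TSA-induced re-expression under KD that is
  not a TF-independent TSA response.
* **recruitment model** — the TF brings HDACs to chromatin.  Losing the TF
  removes deacetylation, so acetylation and expression rise at TF-bound
  genes, and TSA should not change their transcription further.

Each stage is a set intersection; calls carry per-criterion provenance
flags so every admission/exclusion is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .degsets import DEGSet

__all__ = [
    "MechanismInputs",
    "MechanismResult",
    "repression_model",
    "recruitment_model",
]


@dataclass
class MechanismInputs:
    deg_kd: DEGSet  # KD vs control expression
    deg_tsa: DEGSet  # KD+TSA vs KD expression
    ac_down_genes: frozenset[str]  # genes near regions losing H3K27ac in KD
    ac_up_genes: frozenset[str]  # genes near regions gaining H3K27ac in KD
    bound_genes: frozenset[str]  # genes with a TF peak
    tsa_control_responders: frozenset[str]  # TSA DEGs under control KD

    def __post_init__(self) -> None:
        universe = set(self.deg_kd.universe)
        for name in ("ac_down_genes", "ac_up_genes", "bound_genes",
                     "tsa_control_responders"):
            s = getattr(self, name)
            if not set(s) <= universe:
                raise ValueError(f"{name} not contained in the gene universe")


@dataclass
class MechanismResult:
    model: str  # "repression" | "recruitment"
    stages: dict[str, frozenset[str]]  # stage name -> gene set, nested
    provenance: pd.DataFrame  # gene x criterion boolean flags + stage

    def stage(self, name: str) -> frozenset[str]:
        return self.stages[name]

    @property
    def confirmed(self) -> frozenset[str]:
        return self.stages["confirmed"]

    @property
    def candidate(self) -> frozenset[str]:
        return self.stages["candidate"]

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.stages.items()}


def _provenance(flags: dict[str, dict[str, bool]], stage_of: dict[str, str]) -> pd.DataFrame:
    genes = sorted(stage_of)
    rows = []
    for g in genes:
        row = {"gene_id": g, "stage": stage_of[g]}
        row.update({crit: flags[crit].get(g, False) for crit in flags})
        rows.append(row)
    return pd.DataFrame(rows)


def repression_model(inputs: MechanismInputs) -> MechanismResult:
    """Staged repression-model classification.

    candidate = decreased-in-KD ∩ lost-H3K27ac;
    confirmed = candidate ∩ (increased-under-TSA \\ TF-independent TSA
    responders).
    """
    dec = set(inputs.deg_kd.decreased)
    ac_down = set(inputs.ac_down_genes)
    tsa_up = set(inputs.deg_tsa.increased) - set(inputs.tsa_control_responders)
    candidate = dec & ac_down
    confirmed = candidate & tsa_up
    stage_of = {g: "candidate" for g in candidate}
    stage_of.update({g: "confirmed" for g in confirmed})
    flags = {
        "decreased_in_kd": {g: True for g in candidate},
        "ac_down": {g: True for g in candidate},
        "tsa_rescued": {g: g in set(inputs.deg_tsa.increased) for g in candidate},
        "tsa_control_responder": {
            g: g in set(inputs.tsa_control_responders) for g in candidate
        },
    }
    return MechanismResult(
        "repression",
        {"candidate": frozenset(candidate), "confirmed": frozenset(confirmed)},
        _provenance(flags, stage_of),
    )


def recruitment_model(inputs: MechanismInputs) -> MechanismResult:
    """Staged recruitment-model classification.

    candidate = increased-in-KD ∩ gained-H3K27ac;
    bound = candidate ∩ TF-bound genes;
    confirmed = bound genes whose transcription TSA does not alter
    (absent from both TSA DEG directions).
    """
    inc = set(inputs.deg_kd.increased)
    ac_up = set(inputs.ac_up_genes)
    tsa_responders = set(inputs.deg_tsa.increased) | set(inputs.deg_tsa.decreased)
    candidate = inc & ac_up
    bound = candidate & set(inputs.bound_genes)
    confirmed = bound - tsa_responders
    stage_of = {g: "candidate" for g in candidate}
    stage_of.update({g: "bound" for g in bound})
    stage_of.update({g: "confirmed" for g in confirmed})
    flags = {
        "increased_in_kd": {g: True for g in candidate},
        "ac_up": {g: True for g in candidate},
        "tf_bound": {g: g in set(inputs.bound_genes) for g in candidate},
        "tsa_responder": {g: g in tsa_responders for g in candidate},
    }
    return MechanismResult(
        "recruitment",
        {
            "candidate": frozenset(candidate),
            "bound": frozenset(bound),
            "confirmed": frozenset(confirmed),
        },
        _provenance(flags, stage_of),
    )


def write_mechanism_result(result: MechanismResult, tsv_path, json_path=None) -> None:
    result.provenance.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        import json

        with open(json_path, "w") as fh:
            json.dump({"model": result.model, "counts": result.counts()}, fh, indent=2)
            fh.write("\n")
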