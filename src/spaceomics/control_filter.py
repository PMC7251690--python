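"""Exclusion of hardware/preservative artifacts from spaceflight candidates.

Spaceflight studies carry two nuisance exposures besides microgravity: the
flight hardware itself (sealed canisters) and the RNA preservative used for
on-orbit fixation.  Candidates that respond to either nuisance in a matching
ground study are suspect.  Rather than excluding every such gene, a decision
rule retains a candidate whenever spaceflight perturbed it *differently* or
*more strongly* than the control exposure did:

    retain  iff  |LFC_SF - LFC_control| > |LFC_control|
             or  |LFC_SF| > |LFC_control|

with LFC the log2 fold change in the respective study and both inequalities
strict.  The first disjunct is the magnitude of the range of the two values
(max - min), i.e. how far apart the two responses are; the second captures a
stronger same-direction response.  A candidate significant in several
control studies must pass the rule against each of them; candidates absent
from every control significance list pass vacuously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ControlComparison", "passes_decision_rule", "filter_candidates"]

CONTROL_TABLE_COLUMNS = ["feature_id", "log2fc", "significant"]


@dataclass
class ControlComparison:
    """log2FC pairing of one feature between spaceflight and one control study."""

    feature_id: str
    lfc_sf: float
    lfc_control: float
    control_name: str
    significant_in_control: bool = True


def passes_decision_rule(lfc_sf, lfc_control) -> bool | np.ndarray:
    """Evaluate the retention rule; accepts scalars or aligned arrays.

    Raises on NaN input — a missing fold change cannot be adjudicated.
    """
    sf = np.asarray(lfc_sf, dtype=float)
    ctrl = np.asarray(lfc_control, dtype=float)
    if np.isnan(sf).any() or np.isnan(ctrl).any():
        raise ValueError("NaN log2 fold change passed to the decision rule")
    result = (np.abs(sf - ctrl) > np.abs(ctrl)) | (np.abs(sf) > np.abs(ctrl))
    return bool(result) if result.ndim == 0 else result


def filter_candidates(
    sf_records: pd.DataFrame,
    controls: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the decision rule across all control studies.

    Parameters
    ----------
    sf_records
        Spaceflight candidates, indexed by feature id, with a ``log2fc``
        column (the output of the layer's differential caller).
    controls
        Mapping control-study name (e.g. ``"hardware"``, ``"preservative"``)
        to a table with columns ``feature_id``, ``log2fc``, ``significant``.

    Returns
    -------
    retained, audit
        ``retained`` is the surviving subset of ``sf_records``; ``audit``
        records one row per (feature, control) evaluation with the rule
        outcome, plus one row per feature never significant in any control.
    """
    evaluations: list[dict] = []
    failed: set[str] = set()
    seen_in_control: set[str] = set()

    for name, table in controls.items():
        tab = table.loc[table["significant"].astype(bool)]
        dup = tab["feature_id"].duplicated()
        if dup.any():
            dups = sorted(tab.loc[dup, "feature_id"].unique())
            raise ValueError(f"duplicate rows for features {dups} in control study {name!r}")
        ctrl_lfc = tab.set_index("feature_id")["log2fc"]
        shared = sf_records.index.intersection(ctrl_lfc.index)
        for fid in shared:
            sf = float(sf_records.at[fid, "log2fc"])
            cl = float(ctrl_lfc.at[fid])
            ok = passes_decision_rule(sf, cl)
            evaluations.append(
                {
                    "feature_id": fid,
                    "control_name": name,
                    "lfc_sf": sf,
                    "lfc_control": cl,
                    "passes_rule": ok,
                }
            )
            seen_in_control.add(fid)
            if not ok:
                failed.add(fid)

    for fid in sf_records.index.difference(sorted(seen_in_control)):
        evaluations.append(
            {
                "feature_id": fid,
                "control_name": "none",
                "lfc_sf": float(sf_records.at[fid, "log2fc"]),
                "lfc_control": np.nan,
                "passes_rule": True,
            }
        )

    audit = pd.DataFrame(evaluations, columns=["feature_id", "control_name", "lfc_sf", "lfc_control", "passes_rule"])
    retained = sf_records.loc[~sf_records.index.isin(sorted(failed))].copy()
    return retained, audit


def read_control_table(path) -> pd.DataFrame:
    """Read a control-study TSV (feature_id, log2fc, significant)."""
    tab = pd.read_csv(path, sep="\t")
    missing = set(CONTROL_TABLE_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"control table {path} missing columns {sorted(missing)}")
    return tab
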