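"""Candidate lists from annotation joins.

Pure functions of the differential tables and a pre-built per-protein flag
table (drug target, FDA-approved target, cancer/testis antigen, cancer
driver gene): druggable candidates (FDA-approved target AND up-called in at
least one cancer), CT antigen detection/elevation calls, and the
cancer-associated x driver-gene overlap with its per-cancer direction
profile. Live drug-database parsing is out of scope; the annotation table's
column contract is documented in the README.
"""

from __future__ import annotations

import pandas as pd

from .differential import call_matrix, cancer_associated_proteins
from .io_tables import AnnotationTable


def _up_map(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    calls = call_matrix(tables)
    return calls == "up"


def druggable_candidates(
    tables: dict[str, pd.DataFrame], annotation: AnnotationTable
) -> pd.DataFrame:
    """FDA-approved drug targets overexpressed in at least one cancer.

    A candidate must (1) be the target of an FDA-approved drug and (2) be
    called up (fold change > 2 at adjusted p < 0.05) in at least one cancer
    type. Sorted by the maximum log2 fold change over its up-called cancers,
    descending, ties by protein id.
    """
    calls = call_matrix(tables)
    tested = set(calls.index)
    annotated = set(annotation.table["protein_id"])
    if not tested & annotated:
        raise ValueError(
            "annotation and differential tables share no protein ids; "
            "an id mapping table may be required"
        )
    fda = annotation.ids_with("is_fda_approved_target")
    up = _up_map(tables)
    drugs = annotation.drugs_of()

    records = []
    for pid in sorted(tested & fda):
        cancers_up = [c for c in calls.columns if up.at[pid, c]]
        if not cancers_up:
            continue
        max_fc = max(tables[c].at[pid, "log2_fc"] for c in cancers_up)
        records.append(
            {
                "protein_id": pid,
                "fda_approved": True,
                "cancers_up": ",".join(cancers_up),
                "n_cancers_up": len(cancers_up),
                "max_log2_fc": float(max_fc),
                "drugs": drugs.get(pid, ""),
            }
        )
    out = pd.DataFrame(
        records,
        columns=["protein_id", "fda_approved", "cancers_up", "n_cancers_up",
                 "max_log2_fc", "drugs"],
    )
    return out.sort_values(
        ["max_log2_fc", "protein_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def ct_antigen_calls(
    tables: dict[str, pd.DataFrame],
    annotation: AnnotationTable,
    quantified_ids,
) -> pd.DataFrame:
    """Detection and elevation calls for cancer/testis antigens.

    ``detected`` = the antigen is in the quantifiable protein set;
    ``elevated`` = detected and up-called in at least one cancer (the
    elevated cancers are listed).
    """
    ct = annotation.ids_with("is_ct_antigen")
    quantified = set(quantified_ids)
    up = _up_map(tables)
    calls = call_matrix(tables)

    records = []
    for pid in sorted(ct):
        detected = pid in quantified
        if detected and pid in up.index:
            elevated = [c for c in calls.columns if up.at[pid, c]]
        else:
            elevated = []
        records.append(
            {
                "protein_id": pid,
                "detected": detected,
                "elevated": bool(elevated),
                "elevated_cancers": ",".join(elevated),
            }
        )
    return pd.DataFrame(
        records,
        columns=["protein_id", "detected", "elevated", "elevated_cancers"],
    )


def driver_overlap(
    tables: dict[str, pd.DataFrame], annotation: AnnotationTable
) -> pd.DataFrame:
    """Cancer-associated proteins that are products of cancer driver genes.

    Reports, per overlapping protein, the cancers where it is up and where
    it is down (a driver-gene product may well be down-regulated at the
    protein level).
    """
    drivers = annotation.ids_with("is_driver_gene")
    associated = set(cancer_associated_proteins(tables))
    overlap = sorted(associated & drivers)
    calls = call_matrix(tables)

    records = []
    for pid in overlap:
        row = calls.loc[pid]
        ups = [c for c in calls.columns if row[c] == "up"]
        downs = [c for c in calls.columns if row[c] == "down"]
        records.append(
            {
                "protein_id": pid,
                "cancers_up": ",".join(ups),
                "cancers_down": ",".join(downs),
                "direction": "up" if len(ups) >= len(downs) else "down",
            }
        )
    return pd.DataFrame(
        records,
        columns=["protein_id", "cancers_up", "cancers_down", "direction"],
    )
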