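"""Trait and covariate table handling: AQ recoding and cohort validation.

The Autism Spectrum Quotient (AQ) total spans 0–50.  The child form is
scored on a 0–3 Likert scale per item and is dichotomized for comparability
with the adolescent/adult forms: item scores of 0 or 1 count as 0, scores of
2 or 3 count as 1.  Adolescent and adult forms are assumed pre-scored 0–50;
an ``aq_form`` column records provenance so analyses restricted to
parent-report forms remain possible.  SRS-2 scores are ingested directly as
T-scores (population mean 50, SD 10); the raw-to-T conversion tables are
proprietary and out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

AQ_N_ITEMS = 50
AQ_SUBSCALE_COLUMNS = (
    "aq_attention_switching",
    "aq_attention_to_detail",
    "aq_communication",
    "aq_social_skills",
    "aq_imagination",
)


class TraitError(ValueError):
    pass


def recode_child_aq(item_scores: Sequence[int]) -> int:
    """Dichotomize 50 child-form AQ items (0–3 each) into a 0–50 total."""
    items = np.asarray(item_scores)
    if items.shape != (AQ_N_ITEMS,):
        raise TraitError(f"expected exactly {AQ_N_ITEMS} item scores, got {items.size}")
    if not np.issubdtype(items.dtype, np.number) or not np.isin(items, [0, 1, 2, 3]).all():
        raise TraitError("item scores must each be in {0, 1, 2, 3}")
    return int(np.sum(items >= 2))


def _complete_aq(row: pd.Series) -> bool:
    return pd.notna(row.get("aq_total"))


def _complete_srs(row: pd.Series) -> bool:
    return pd.notna(row.get("srs2_t"))


def validate_traits(
    trait_table: pd.DataFrame,
    stability_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate and filter the trait table against inclusion criteria.

    A participant is retained iff they have at least one stability record
    and a complete AQ total or SRS-2 T-score.  Missing values are preserved
    (no imputation): a participant with AQ only enters AQ models and is
    absent from SRS-2 models, handled downstream by per-model missingness.
    Returns (clean table, issue report); idempotent on its own output.
    """
    df = trait_table.copy()
    if "participant_id" not in df.columns:
        raise TraitError("trait table must have a participant_id column")
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if len(dup):
        raise TraitError(f"duplicate participant ids: {sorted(dup.unique())}")
    for col in ("aq_total", "srs2_t", "age", "vci"):
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                raise TraitError(f"non-numeric values in column {col!r}: {exc}") from None
    if "aq_total" in df.columns:
        bad = df["aq_total"].dropna()
        if ((bad < 0) | (bad > 50)).any():
            raise TraitError("aq_total must lie in [0, 50]")
    present = set(AQ_SUBSCALE_COLUMNS) & set(df.columns)
    if len(present) == len(AQ_SUBSCALE_COLUMNS) and "aq_total" in df.columns:
        subs = df[list(AQ_SUBSCALE_COLUMNS)]
        full = subs.notna().all(axis=1) & df["aq_total"].notna()
        mismatch = full & (subs.sum(axis=1) != df["aq_total"])
        if mismatch.any():
            raise TraitError(
                f"AQ subscales do not sum to aq_total for: "
                f"{df.loc[mismatch, 'participant_id'].tolist()}"
            )

    with_neural = set(stability_table["participant_id"].unique())
    issues = []
    keep = []
    for _, row in df.iterrows():
        pid = row["participant_id"]
        has_trait = _complete_aq(row) or _complete_srs(row)
        if pid not in with_neural:
            issues.append({"participant_id": pid, "issue": "no stability records"})
        elif not has_trait:
            issues.append({"participant_id": pid, "issue": "no complete AQ or SRS-2 score"})
        else:
            keep.append(pid)
    clean = df[df["participant_id"].isin(keep)].reset_index(drop=True)
    report = pd.DataFrame(issues, columns=["participant_id", "issue"])
    return clean, report
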