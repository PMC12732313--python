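"""Domain-architecture classification from ranked profile-HMM hits.

A protein's architecture is read off the ranking of its hmmscan-style
hits to three diagnostic models: COG2605 (monofunctional fucokinase,
FUK), PF07959 (GDP-fucose pyrophosphorylase, GFPP) and PRK13412
(full-length bifunctional FKP).  Membership rules:

* FUK set: top model is COG2605 or PRK13412, or PF07959 together with
  one of {COG2605, PRK13412} occupy the top two ranks.
* GFPP set: top model is PF07959 or PRK13412, or COG2605 together with
  one of {PF07959, PRK13412} occupy the top two ranks.
* FKP set: all three diagnostic models occupy the top three ranks.

Memberships are then revoked for sequences shorter than a per-dataset
minimum (333 residues for FUKs, 406 for GFPPs, 739 for full-length FKPs)
or longer than a common maximum (1745 residues).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .simulate import FUK_MODEL, GFPP_MODEL, FKP_MODEL

log = logging.getLogger(__name__)

TARGET_MODELS = frozenset({FUK_MODEL, GFPP_MODEL, FKP_MODEL})

__all__ = [
    "LengthThresholds",
    "HitTableError",
    "read_hit_table",
    "rank_models",
    "classify_architecture",
    "summarize_calls",
]


@dataclass(frozen=True)
class LengthThresholds:
    """Per-dataset length filters (residues)."""

    min_fuk: int = 333
    min_gfpp: int = 406
    min_fkp: int = 739
    max_len: int = 1745

    @classmethod
    def figure_preset(cls) -> "LengthThresholds":
        """Alternative preset with the 745-residue full-length minimum."""
        return cls(min_fkp=745)


class HitTableError(ValueError):
    """Raised for malformed hit-table input."""


_REQUIRED_COLS = ("query_id", "model_id", "score")


def read_hit_table(path) -> pd.DataFrame:
    """Read a TSV hit table with columns query_id, model_id, score.

    Malformed score entries are reported with their 1-based data line
    numbers.  An empty file yields an empty table with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        log.warning("hit table %s is empty", path)
        return pd.DataFrame(columns=list(_REQUIRED_COLS)).astype({"score": float})
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise HitTableError(f"hit table {path} is missing column(s): {', '.join(missing)}")
    if df.empty:
        log.warning("hit table %s has a header but no rows", path)
        return df.astype({"score": float})
    score = pd.to_numeric(df["score"], errors="coerce")
    bad = score.index[score.isna()]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-basing
        raise HitTableError(f"non-numeric score values at line(s) {lines}")
    df = df.assign(score=score.astype(float))
    if not (score.ge(0) & score.lt(float("inf"))).all():
        raise HitTableError("scores must be finite and >= 0")
    if df.duplicated(subset=["query_id", "model_id"]).any():
        raise HitTableError("duplicate (query_id, model_id) pairs")
    return df


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_model_id(model_id: str) -> str:
    """Trim a trailing version suffix and uppercase (``PF07959.22 -> PF07959``)."""
    return _VERSION_SUFFIX.sub("", model_id.strip()).upper()


def rank_models(hits: pd.DataFrame) -> dict[str, list[str]]:
    """Per query, models sorted by descending score, ties lexicographic."""
    ranked: dict[str, list[str]] = {}
    for qid, grp in hits.groupby("query_id", sort=False):
        order = sorted(
            zip(grp["model_id"], grp["score"]), key=lambda t: (-t[1], t[0])
        )
        ranked[qid] = [m for m, _ in order]
    return ranked


def _memberships(models: list[str]) -> tuple[bool, bool, bool]:
    norm = [normalize_model_id(m) for m in models]
    top1 = set(norm[:1])
    top2 = set(norm[:2])
    top3 = set(norm[:3])
    in_fuk = bool(top1 & {FUK_MODEL, FKP_MODEL}) or (
        GFPP_MODEL in top2 and bool(top2 & {FUK_MODEL, FKP_MODEL})
    )
    in_gfpp = bool(top1 & {GFPP_MODEL, FKP_MODEL}) or (
        FUK_MODEL in top2 and bool(top2 & {GFPP_MODEL, FKP_MODEL})
    )
    in_fkp = len(models) >= 3 and TARGET_MODELS <= top3
    return in_fuk, in_gfpp, in_fkp


def classify_architecture(
    ranked: dict[str, list[str]],
    lengths: dict[str, int],
    thresholds: LengthThresholds = LengthThresholds(),
) -> pd.DataFrame:
    """Assign FUK/GFPP/FKP dataset memberships with length filtering.

    Returns one row per query with raw rule memberships, the post-filter
    memberships (``in_*_set``), and per-dataset length_pass flags.
    Proteins with no hits belong to no set.
    """
    missing = [q for q in ranked if q not in lengths]
    if missing:
        raise KeyError(f"no length for query id(s): {missing[:5]}")
    rows = []
    for qid, models in ranked.items():
        length = lengths[qid]
        fuk, gfpp, fkp = _memberships(models) if models else (False, False, False)
        ok_max = length <= thresholds.max_len
        pass_fuk = thresholds.min_fuk <= length and ok_max
        pass_gfpp = thresholds.min_gfpp <= length and ok_max
        pass_fkp = thresholds.min_fkp <= length and ok_max
        rows.append(
            {
                "query_id": qid,
                "length": length,
                "top_models": ",".join(models[:3]),
                "rule_fuk": fuk,
                "rule_gfpp": gfpp,
                "rule_fkp": fkp,
                "length_pass_fuk": pass_fuk,
                "length_pass_gfpp": pass_gfpp,
                "length_pass_fkp": pass_fkp,
                "in_fuk_set": fuk and pass_fuk,
                "in_gfpp_set": gfpp and pass_gfpp,
                "in_fkp_set": fkp and pass_fkp,
            }
        )
    return pd.DataFrame(rows)


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of each membership combination plus per-set totals."""
    combos = []
    for fuk in (False, True):
        for gfpp in (False, True):
            for fkp in (False, True):
                if calls.empty:
                    n = 0
                else:
                    n = int(
                        (
                            (calls["in_fuk_set"] == fuk)
                            & (calls["in_gfpp_set"] == gfpp)
                            & (calls["in_fkp_set"] == fkp)
                        ).sum()
                    )
                combos.append(
                    {"in_fuk_set": fuk, "in_gfpp_set": gfpp, "in_fkp_set": fkp, "count": n}
                )
    out = pd.DataFrame(combos)
    out.attrs["totals"] = {
        "fuk_set": 0 if calls.empty else int(calls["in_fuk_set"].sum()),
        "gfpp_set": 0 if calls.empty else int(calls["in_gfpp_set"].sum()),
        "fkp_set": 0 if calls.empty else int(calls["in_fkp_set"].sum()),
        "n_proteins": len(calls),
    }
    return out
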