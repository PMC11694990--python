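"""Per-case feature table of compression indices.

Nine index families are computed per 10-minute segment and per component
(trend, residual):

* ``fetal/maternal/maternal-fetal compression ratio`` — byte-compressor
  redundancy of the segment (the maternal-fetal variant compresses the
  fetal-then-maternal byte concatenation of the simultaneous segments);
* ``maternal-fetal NRC`` — NRC(fetal || maternal) on the simultaneous
  quantized segments (x = fetal, y = maternal: the fetus's dependence on the
  mother);
* ``fetal/maternal NRC`` — NRC of a segment given the same channel's
  reference segment (the first segment after the 30-minute drop), tracking
  each series' self-similarity over time;
* ``maternal-fetal NCD`` — compressor distance between the simultaneous
  segments; ``fetal/maternal NCD`` — distance of a segment to the same
  channel's reference segment.

Feature values from the first 30 minutes are eliminated (short recordings
make that window inconsistent across subjects), so columns cover slots
h1-d..h2-f; over-time families additionally exclude the reference segment
itself (a self-comparison carries no information), covering h1-e..h2-f.
Column names follow the ``<family> — <hour>-<slot> — <component>`` pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compression import FCMConfig, compression_ratio, fit_fcm, ncd, nrc, relative_code_length
from .preprocessing import SEGMENT_LABELS, TrendConfig, preprocess_subject
from .quantization import DEFAULT_ALPHABET, fit_lloyd_max, quantize

FAMILIES = [
    "fetal compression ratio",
    "maternal compression ratio",
    "maternal-fetal compression ratio",
    "fetal NRC",
    "maternal NRC",
    "maternal-fetal NRC",
    "fetal NCD",
    "maternal NCD",
    "maternal-fetal NCD",
]
#: families compared over time against the reference segment
OVER_TIME_FAMILIES = ["fetal NRC", "maternal NRC", "fetal NCD", "maternal NCD"]
MF_FAMILIES = [f for f in FAMILIES if f.startswith("maternal-fetal")]
COMPONENTS = ["trend", "residual"]

#: slots removed by the first-30-minutes rule
EARLY_SLOTS = ("h1-a", "h1-b", "h1-c")

#: serialization offset for residual components (centred, signed values)
RESIDUAL_OFFSET = 128.0

META_COLUMNS = ["group", "origin"]


def column_name(family: str, label: str, component: str) -> str:
    return f"{family} — {label} — {component}"


def _segment_offset(component: str) -> float:
    return RESIDUAL_OFFSET if component == "residual" else 0.0


def subject_features(record, trend_cfg: TrendConfig | None = None,
                     fcm_cfg: FCMConfig | None = None,
                     alphabet_size: int = DEFAULT_ALPHABET,
                     families=None) -> dict:
    """Compute one subject's feature row (column name -> value).

    One Lloyd-Max quantizer is fitted per (channel, component) on the full
    preprocessed series and shared across segments.  ``families`` restricts
    the computed index families (default: all nine).
    """
    families = list(families) if families is not None else list(FAMILIES)
    fcm_cfg = fcm_cfg or FCMConfig(alphabet_size=alphabet_size)
    prep = preprocess_subject(record, trend_cfg)

    seg_map = {}  # (channel, component) -> {label: samples}
    sym_map = {}  # (channel, component) -> {label: SymbolSequence}
    need_symbols = any("NRC" in f for f in families)
    for key, segs in prep["segments"].items():
        seg_map[key] = {s.label: s.samples for s in segs}
        if need_symbols:
            q = fit_lloyd_max(prep["series"][key], alphabet_size)
            sym_map[key] = {
                s.label: quantize(s.samples, q, source=(record.subject_id, *key, s.label))
                for s in segs
            }

    row = {}
    for component in COMPONENTS:
        fetal = seg_map[("fetal", component)]
        maternal = seg_map[("maternal", component)]
        labels = [lab for lab in SEGMENT_LABELS if lab in fetal and lab in maternal]
        kept = [lab for lab in labels if lab not in EARLY_SLOTS]
        if not kept:
            continue
        ref_label = kept[0]  # first segment after the 30-minute drop
        off = _segment_offset(component)

        if need_symbols:
            fsym = sym_map[("fetal", component)]
            msym = sym_map[("maternal", component)]
            if {"fetal NRC", "maternal NRC"} & set(families):
                ref_models = {
                    "fetal": fit_fcm(fsym[ref_label], fcm_cfg),
                    "maternal": fit_fcm(msym[ref_label], fcm_cfg),
                }
        for lab in kept:
            if "fetal compression ratio" in families:
                row[column_name("fetal compression ratio", lab, component)] = (
                    compression_ratio(fetal[lab], offset=off))
            if "maternal compression ratio" in families:
                row[column_name("maternal compression ratio", lab, component)] = (
                    compression_ratio(maternal[lab], offset=off))
            if "maternal-fetal compression ratio" in families:
                row[column_name("maternal-fetal compression ratio", lab, component)] = (
                    compression_ratio(np.concatenate([fetal[lab], maternal[lab]]),
                                      offset=off))
            if "maternal-fetal NRC" in families:
                row[column_name("maternal-fetal NRC", lab, component)] = nrc(
                    fsym[lab], msym[lab], fcm_cfg)
            if "maternal-fetal NCD" in families:
                row[column_name("maternal-fetal NCD", lab, component)] = ncd(
                    fetal[lab], maternal[lab], offset=off)
            if lab != ref_label:
                for fam in ("fetal NRC", "maternal NRC"):
                    if fam in families:
                        sym = fsym if fam.startswith("fetal") else msym
                        cl = relative_code_length(
                            sym[lab], ref_models[fam.split()[0]])
                        norm = cl.n_symbols * np.log2(fcm_cfg.alphabet_size)
                        row[column_name(fam, lab, component)] = cl.bits / norm
                if "fetal NCD" in families:
                    row[column_name("fetal NCD", lab, component)] = ncd(
                        fetal[lab], fetal[ref_label], offset=off)
                if "maternal NCD" in families:
                    row[column_name("maternal NCD", lab, component)] = ncd(
                        maternal[lab], maternal[ref_label], offset=off)
    return row


def cohort_feature_table(subjects, trend_cfg=None, fcm_cfg=None,
                         alphabet_size: int = DEFAULT_ALPHABET,
                         families=None) -> pd.DataFrame:
    """Feature rows for a cohort, with group and origin provenance columns.

    Columns are ordered canonically (family, component, hour, slot); rows are
    indexed by subject id.  A subject missing a column (short recording)
    yields NaN there.
    """
    rows, index = [], []
    for rec in subjects:
        row = subject_features(rec, trend_cfg, fcm_cfg, alphabet_size, families)
        row["group"] = rec.group
        row["origin"] = rec.origin
        rows.append(row)
        index.append(rec.subject_id)
    table = pd.DataFrame(rows, index=index)
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    ordered = _canonical_order(feature_cols)
    return table[ordered + META_COLUMNS]


def _canonical_order(columns):
    def key(col):
        family, label, component = [p.strip() for p in col.split("—")]
        return (FAMILIES.index(family), COMPONENTS.index(component),
                SEGMENT_LABELS.index(label))
    return sorted(columns, key=key)


def collinearity_filter(table: pd.DataFrame, threshold: float = 0.5,
                        train_index=None):
    """Greedy redundancy reduction: keep, in canonical column order, only
    columns whose |Pearson r| with every already-kept column is <= threshold.

    Correlations are computed on ``train_index`` rows only (all rows if
    None); constant columns are dropped first.  Returns the retained column
    list, to be applied to train and test alike.
    """
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    sub = table.loc[train_index, feature_cols] if train_index is not None \
        else table[feature_cols]
    variances = sub.var(axis=0, ddof=0)
    usable = [c for c in feature_cols if variances[c] > 0 and sub[c].notna().all()]
    corr = sub[usable].corr().abs()
    kept = []
    for col in usable:
        if all(corr.loc[col, prev] <= threshold for prev in kept):
            kept.append(col)
    return kept


FEATURE_SET_DEFS = {
    "A": (FAMILIES, ["trend"]),
    "B": (FAMILIES, ["residual"]),
    "C": ([f for f in FAMILIES if not f.startswith("maternal-fetal")], ["trend"]),
    "D": ([f for f in FAMILIES if not f.startswith("maternal-fetal")], ["residual"]),
    "E": (MF_FAMILIES, ["trend"]),
    "F": (MF_FAMILIES, ["residual"]),
    "G": (["maternal-fetal NRC", "maternal-fetal NCD"], ["trend"]),
    "H": (["maternal-fetal NRC", "maternal-fetal NCD"], ["residual"]),
    "I": (MF_FAMILIES, ["trend", "residual"]),
}


def select_feature_set(table: pd.DataFrame, test_id: str) -> pd.DataFrame:
    """Columns for one of the nine feature-set tests A..I (plus metadata)."""
    if test_id not in FEATURE_SET_DEFS:
        raise ValueError(f"unknown test id {test_id!r}; expected A..I")
    families, components = FEATURE_SET_DEFS[test_id]
    cols = []
    for col in table.columns:
        if col in META_COLUMNS:
            continue
        family, _, component = [p.strip() for p in col.split("—")]
        if family in families and component in components:
            cols.append(col)
    meta = [c for c in META_COLUMNS if c in table.columns]
    return table[cols + meta]
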