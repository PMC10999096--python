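"""Bioactivity curation: parsing, cleaning, aggregation, labeling, splitting.

The pipeline follows the data-preparation conventions used when building
target-specific scoring functions from public bioactivity exports
(ChEMBL-style tables):

* keep only records whose standard relation is certain (``=``) or a
  lower-bound censor (``>``, which marks the compound inactive);
* drop rows with missing SMILES (counted);
* transform potencies to pIC50 = −log10(IC50 × 10⁻⁹) with IC50 in nM;
* average replicate measurements and reject compounds whose replicate
  dispersion is too high (population SD on the pIC50 scale ≥ 2 by
  default — see :func:`aggregate_compound`);
* label actives at pIC50 ≥ 6 (the 1 µM threshold); inactives carry a
  fixed regression target of pIC50 = 2;
* partition by assay annotation: biochemical-only compounds train the
  model, cell-assayed compounds form the true test set.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("targetsf.curation")

__all__ = [
    "AssayKind",
    "ActivityRecord",
    "CuratedCompound",
    "DataSplit",
    "CurationLog",
    "load_activity_records",
    "filter_certain",
    "ic50_to_pic50",
    "standardize_structure",
    "aggregate_compound",
    "label_compound",
    "curate",
    "split_by_assay",
]

ACTIVITY_THRESHOLD_PIC50 = 6.0  # 1 µM
INACTIVE_REGRESSION_TARGET = 2.0
DEFAULT_SD_THRESHOLD = 2.0  # log units on the pIC50 scale

_RELATION_ALIASES = {
    "=": "eq", "eq": "eq",
    ">": "gt", ">=": "gt", "gt": "gt",
    "<": "lt", "<=": "lt", "lt": "lt",
    "~": "approx", "approx": "approx",
}

_ASSAY_ALIASES = {
    "biochemical": "biochemical", "b": "biochemical", "enzymatic": "biochemical",
    "cellular": "cellular", "cell": "cellular", "f": "cellular",
    "binding": "binding", "kd": "binding", "biophysical": "binding",
}

DEFAULT_COLUMN_MAP = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "relation": "relation",
    "value_nM": "value_nM",
    "assay_kind": "assay_kind",
}


class AssayKind(str, Enum):
    BIOCHEMICAL = "biochemical"
    CELLULAR = "cellular"
    BINDING = "binding"


@dataclass(frozen=True)
class ActivityRecord:
    """One measured bioactivity data point."""

    compound_id: str
    smiles: str
    assay_kind: str
    relation: str  # normalized: eq/gt/lt/approx
    value_nM: float

    def __post_init__(self):
        if self.value_nM <= 0 or not math.isfinite(self.value_nM):
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")


@dataclass
class CuratedCompound:
    """Aggregated, standardized, labeled compound."""

    compound_id: str
    canonical_smiles: str
    pIC50: float  # regression target: measured for actives, 2.0 for inactives
    label: str  # "active" | "inactive"
    has_biochemical: bool = False
    has_cellular: bool = False
    has_binding: bool = False
    biochemical_pIC50: float | None = None
    cellular_pIC50: float | None = None
    measured_pIC50: float | None = None

    @property
    def is_active(self) -> bool:
        return self.label == "active"


@dataclass
class CurationLog:
    """Row/compound-level bookkeeping of the curation pipeline."""

    n_rows: int = 0
    n_missing_smiles: int = 0
    n_bad_value: int = 0
    n_uncertain_relation: int = 0
    n_unparsable_smiles: int = 0
    n_dispersion_rejected: int = 0
    n_no_assay_flag: int = 0
    n_ambiguous_test_label: int = 0
    rejected_compounds: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class DataSplit:
    """Assay-defined train/test partition plus decoy bookkeeping."""

    training: list[CuratedCompound]
    test_true: list[CuratedCompound]
    test_decoys: list[str] = field(default_factory=list)
    excluded: list[CuratedCompound] = field(default_factory=list)

    def summary(self) -> dict:
        """Partition composition counts (the split manifest payload)."""
        tr_a = sum(c.is_active for c in self.training)
        te_a = sum(c.is_active for c in self.test_true)
        return {
            "training_actives": tr_a,
            "training_inactives": len(self.training) - tr_a,
            "training_total": len(self.training),
            "test_actives": te_a,
            "test_inactives": len(self.test_true) - te_a,
            "test_true_total": len(self.test_true),
            "test_decoys": len(self.test_decoys),
            "test_total": len(self.test_true) + len(self.test_decoys),
            "excluded": len(self.excluded),
        }

    def manifest(self) -> dict:
        """JSON-ready manifest listing ids, labels and targets."""
        return {
            "summary": self.summary(),
            "training": [
                {"compound_id": c.compound_id, "label": c.label,
                 "pIC50": c.pIC50} for c in self.training],
            "test_true": [
                {"compound_id": c.compound_id, "label": c.label,
                 "pIC50": c.pIC50} for c in self.test_true],
            "test_decoys": list(self.test_decoys),
        }

    @staticmethod
    def dissimilar_composition(n_actives_kept: int, n_inactives_kept: int,
                               n_decoys_kept: int) -> dict:
        """Bookkeeping for a similarity-filtered test set."""
        return {
            "test_actives": n_actives_kept,
            "test_inactives": n_inactives_kept,
            "test_decoys": n_decoys_kept,
            "test_total": n_actives_kept + n_inactives_kept + n_decoys_kept,
        }


# ---------------------------------------------------------------------------
# Loading and filtering


def load_activity_records(source, column_map: dict | None = None,
                          log: CurationLog | None = None
                          ) -> list[ActivityRecord]:
    """Parse a delimited activity table into records.

    ``source`` may be a path, a text stream, or a DataFrame. The header
    must name the five required columns (``column_map`` translates
    non-default layouts). Rows with missing SMILES are dropped and
    counted; rows with non-numeric or non-positive potency are rejected
    with a log entry. Relations other than =/> are kept here (they are
    removed by :func:`filter_certain`).
    """
    log = log if log is not None else CurationLog()
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            text = Path(source).read_text()
        elif hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
        if not text.strip():
            logger.warning("empty activity table")
            return []
        sep = "\t" if "\t" in text.splitlines()[0] else ","
        df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    missing_cols = [v for v in cmap.values() if v not in df.columns]
    if missing_cols:
        raise KeyError(
            f"activity table lacks required columns {missing_cols}; "
            f"available: {list(df.columns)}")
    records: list[ActivityRecord] = []
    for _, row in df.iterrows():
        log.n_rows += 1
        smiles = row[cmap["smiles"]]
        if smiles is None or (isinstance(smiles, float) and math.isnan(smiles)) \
                or not str(smiles).strip():
            log.n_missing_smiles += 1
            continue
        try:
            value = float(row[cmap["value_nM"]])
            if value <= 0 or not math.isfinite(value):
                raise ValueError
        except (TypeError, ValueError):
            log.n_bad_value += 1
            logger.info("rejecting row with non-positive/non-numeric value: %r",
                        row.get(cmap["value_nM"]))
            continue
        relation = _RELATION_ALIASES.get(
            str(row[cmap["relation"]]).strip().lower(),
            str(row[cmap["relation"]]).strip().lower())
        assay = _ASSAY_ALIASES.get(
            str(row[cmap["assay_kind"]]).strip().lower(), None)
        if assay is None:
            assay = str(row[cmap["assay_kind"]]).strip().lower()
        records.append(ActivityRecord(
            compound_id=str(row[cmap["compound_id"]]).strip(),
            smiles=str(smiles).strip(),
            assay_kind=assay,
            relation=relation,
            value_nM=value))
    return records


def filter_certain(records: Iterable[ActivityRecord],
                   log: CurationLog | None = None) -> list[ActivityRecord]:
    """Keep only certain (=) and lower-bound (>) records.

    ``>`` records are inactive candidates regardless of their value;
    everything else (<, ~, unknown) is discarded. Idempotent.
    """
    kept = []
    for r in records:
        if r.relation in ("eq", "gt"):
            kept.append(r)
        elif log is not None:
            log.n_uncertain_relation += 1
    return kept


def ic50_to_pic50(value_nM: float) -> float:
    """pIC50 = −log10(IC50 × 10⁻⁹), IC50 in nanomolar."""
    if value_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {value_nM}")
    return 9.0 - math.log10(value_nM)


def pic50_to_ic50(pic50: float) -> float:
    """Inverse transform, returning IC50 in nanomolar."""
    return 10.0 ** (9.0 - pic50)


# ---------------------------------------------------------------------------
# Structure standardization


def standardize_structure(smiles: str) -> str:
    """Open standardization pipeline: fragment-keep, neutralize, tautomer.

    Keeps the largest organic fragment (salt/metal strip), neutralizes
    charges where chemically valid, canonicalizes the tautomer and emits
    canonical SMILES. Deterministic. Raises ``ValueError`` on unparsable
    input.
    """
    from rdkit import Chem
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = rdMolStandardize.LargestFragmentChooser(preferOrganic=True).choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    mol = rdMolStandardize.TautomerEnumerator().Canonicalize(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Aggregation and labeling


class AggregationError(ValueError):
    def __init__(self, compound_id: str, reason: str):
        self.compound_id = compound_id
        self.reason = reason
        super().__init__(f"{compound_id}: {reason}")


def aggregate_compound(records: Sequence[ActivityRecord],
                       sd_threshold: float = DEFAULT_SD_THRESHOLD,
                       sd_scale: str = "pic50",
                       mean_scale: str = "nM") -> CuratedCompound:
    """Aggregate all records of one compound into a labeled compound.

    Certain (=) replicate potencies are averaged — by default the
    arithmetic mean of IC50 in nM, then log-transformed
    (``mean_scale='pic50'`` averages on the log scale instead). The
    replicate-dispersion filter rejects the compound when the population
    standard deviation (``ddof=0``) exceeds ``sd_threshold``; by default
    the SD is taken on the pIC50 (log) scale, where a threshold of 2 log
    units is meaningful across the micromolar range (``sd_scale='nM'``
    applies it to raw nanomolar values instead).

    Any lower-bound (>) record marks the compound inactive regardless of
    value. Assay-kind flags are the union over records; per-assay-kind
    pIC50 aggregates are retained for the assay-based split.
    """
    if not records:
        raise AggregationError("?", "no records")
    cid = records[0].compound_id
    if any(r.compound_id != cid for r in records):
        raise AggregationError(cid, "records from multiple compounds")
    eq = [r for r in records if r.relation == "eq"]
    gt = [r for r in records if r.relation == "gt"]
    if not eq and not gt:
        raise AggregationError(cid, "no certain or lower-bound records")

    def _mean_pic50(rs):
        if mean_scale == "nM":
            return ic50_to_pic50(float(np.mean([r.value_nM for r in rs])))
        return float(np.mean([ic50_to_pic50(r.value_nM) for r in rs]))

    measured = None
    if eq:
        # replicates are same-assay-kind measurements; potencies from
        # different assay types differ systematically and are not
        # dispersion-filtered against each other
        by_kind: dict[str, list[ActivityRecord]] = {}
        for r in eq:
            by_kind.setdefault(r.assay_kind, []).append(r)
        for kind, kind_eq in by_kind.items():
            if len(kind_eq) < 2:
                continue
            if sd_scale == "pic50":
                disp = float(np.std([ic50_to_pic50(r.value_nM)
                                     for r in kind_eq]))
            else:
                disp = float(np.std([r.value_nM for r in kind_eq]))
            if disp >= sd_threshold:
                raise AggregationError(
                    cid, f"{kind} replicate dispersion "
                         f"{disp:.3f} >= {sd_threshold}")
        measured = _mean_pic50(eq)

    kinds = {r.assay_kind for r in records}
    per_kind: dict[str, float | None] = {}
    for kind in ("biochemical", "cellular"):
        kind_eq = [r for r in eq if r.assay_kind == kind]
        per_kind[kind] = _mean_pic50(kind_eq) if kind_eq else None

    compound = CuratedCompound(
        compound_id=cid,
        canonical_smiles=records[0].smiles,
        pIC50=float("nan"),
        label="inactive",
        has_biochemical="biochemical" in kinds,
        has_cellular="cellular" in kinds,
        has_binding="binding" in kinds,
        biochemical_pIC50=per_kind["biochemical"],
        cellular_pIC50=per_kind["cellular"],
        measured_pIC50=measured)
    return label_compound(compound, force_inactive=bool(gt))


def label_compound(compound: CuratedCompound,
                   force_inactive: bool = False) -> CuratedCompound:
    """Assign the active/inactive label and the regression target.

    Active iff the certain-data aggregate pIC50 is ≥ 6 (IC50 ≤ 1 µM) and
    no lower-bound record forces inactivity. Inactives carry the fixed
    regression target pIC50 = 2.
    """
    measured = compound.measured_pIC50
    if (not force_inactive and measured is not None
            and measured >= ACTIVITY_THRESHOLD_PIC50):
        compound.label = "active"
        compound.pIC50 = measured
    else:
        compound.label = "inactive"
        compound.pIC50 = INACTIVE_REGRESSION_TARGET
    return compound


def curate(records: Iterable[ActivityRecord],
           standardize: bool = True,
           sd_threshold: float = DEFAULT_SD_THRESHOLD,
           sd_scale: str = "pic50",
           mean_scale: str = "nM",
           log: CurationLog | None = None) -> list[CuratedCompound]:
    """Full record-level pipeline: filter, standardize, aggregate, label."""
    log = log if log is not None else CurationLog()
    records = filter_certain(records, log)
    by_compound: dict[str, list[ActivityRecord]] = {}
    for r in records:
        by_compound.setdefault(r.compound_id, []).append(r)
    out = []
    for cid, group in by_compound.items():
        try:
            compound = aggregate_compound(group, sd_threshold=sd_threshold,
                                          sd_scale=sd_scale,
                                          mean_scale=mean_scale)
        except AggregationError as exc:
            log.n_dispersion_rejected += 1
            log.rejected_compounds.append((cid, exc.reason))
            continue
        if standardize:
            try:
                compound.canonical_smiles = standardize_structure(
                    compound.canonical_smiles)
            except ValueError:
                log.n_unparsable_smiles += 1
                log.rejected_compounds.append((cid, "unparsable SMILES"))
                continue
        out.append(compound)
    return out


# ---------------------------------------------------------------------------
# Assay-based splitting


def split_by_assay(compounds: Iterable[CuratedCompound],
                   include_binding_only: bool = False,
                   log: CurationLog | None = None) -> DataSplit:
    """Partition curated compounds by assay annotation.

    Training: biochemical but not cellular potency. Test: cell-assayed
    compounds — a test active needs both cellular and biochemical pIC50
    ≥ 6, a test inactive is decided by cellular potency alone (< 6).
    Cell-actives lacking confirmed biochemical activity are ambiguous
    under those two rules and are excluded (logged). Compounds with only
    binding-affinity (Kd) data are excluded unless
    ``include_binding_only`` (then they join training).
    """
    log = log if log is not None else CurationLog()
    training, test_true, excluded = [], [], []
    for c in compounds:
        if c.has_biochemical and not c.has_cellular:
            training.append(c)
        elif c.has_cellular:
            cell = c.cellular_pIC50
            bio = c.biochemical_pIC50
            if c.label != "inactive" and cell is not None \
                    and cell >= ACTIVITY_THRESHOLD_PIC50:
                if bio is not None and bio >= ACTIVITY_THRESHOLD_PIC50:
                    test_true.append(_with_label(c, "active", cell))
                else:
                    log.n_ambiguous_test_label += 1
                    excluded.append(c)
            else:
                test_true.append(_with_label(c, "inactive",
                                             INACTIVE_REGRESSION_TARGET))
        elif c.has_binding and include_binding_only:
            training.append(c)
        else:
            log.n_no_assay_flag += 1
            excluded.append(c)
    return DataSplit(training=training, test_true=test_true,
                     excluded=excluded)


def _with_label(c: CuratedCompound, label: str, target: float) -> CuratedCompound:
    c.label = label
    c.pIC50 = target if label == "inactive" else (
        c.cellular_pIC50 if c.cellular_pIC50 is not None else target)
    return c
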