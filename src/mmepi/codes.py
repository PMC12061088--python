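"""Code-list configuration and ICD-10 pattern matching.

Every identification rule in this package is expressed over code lists:
ICD-10 diagnosis prefixes (multiple myeloma ``C90*``, the exclusion
indications for immunomodulatory drugs), drug identifiers, and procedure
codes for protein electrophoresis and stem-cell transplantation.  The
reference lists used on the French claims warehouse are not public, so the
package ships documented *example* lists and resolves every code through a
:class:`CodeListConfig`, which can be replaced wholesale from a YAML file.

ICD-10 codes are stored without dots (``"C900"``, not ``"C90.0"``), the way
claims extracts carry them; :func:`normalize_icd10` strips dots on input.
A trailing ``*`` in a pattern denotes prefix matching.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, field_validator

__all__ = [
    "normalize_icd10",
    "match_icd10",
    "match_any_icd10",
    "icd10_mask",
    "CodeListConfig",
    "DRUG_CLASSES",
    "PROCEDURE_KINDS",
]

DRUG_CLASSES = ("mm_specific", "lenalidomide", "thalidomide", "chemotherapy", "other")
PROCEDURE_KINDS = ("SPEP", "UPEP", "ASCT", "other")

_ICD10_RE = re.compile(r"^[A-Z][A-Z0-9]*$")


def normalize_icd10(code: str) -> str:
    """Return *code* upper-cased with dots removed (``"c90.0"`` → ``"C900"``)."""
    return str(code).replace(".", "").strip().upper()


def match_icd10(code: str, pattern: str) -> bool:
    """True iff *code* matches *pattern*.

    *pattern* is either a literal code (exact match) or a prefix ending in
    ``*`` (``"C90*"`` matches ``"C90"``, ``"C900"``, ``"C909"`` …).
    """
    if not pattern:
        raise ValueError("empty ICD-10 pattern")
    code = normalize_icd10(code)
    pattern = normalize_icd10(pattern)
    if pattern.endswith("*"):
        return code.startswith(pattern[:-1])
    return code == pattern


def match_any_icd10(code: str, patterns: Iterable[str]) -> bool:
    return any(match_icd10(code, p) for p in patterns)


def icd10_mask(codes: pd.Series, patterns: Sequence[str]) -> np.ndarray:
    """Vectorized :func:`match_icd10` over a Series against several patterns."""
    if len(codes) == 0:
        return np.zeros(0, dtype=bool)
    parts = []
    for p in patterns:
        if not p:
            raise ValueError("empty ICD-10 pattern")
        p = normalize_icd10(p)
        parts.append(re.escape(p[:-1]) if p.endswith("*") else re.escape(p) + "$")
    if not parts:
        return np.zeros(len(codes), dtype=bool)
    regex = "^(?:" + "|".join(parts) + ")"
    return codes.astype(str).str.replace(".", "", regex=False).str.upper().str.match(regex).to_numpy()


class CodeListConfig(BaseModel):
    """Configured vocabularies mapping raw codes to the classes the rules use.

    The defaults are documented examples (ATC-style drug identifiers and
    synthetic procedure codes) sufficient to run the simulator and the
    pipeline end to end; they are not an authoritative transcription of any
    national code list.
    """

    mm_icd10: list[str] = ["C90*"]
    # Indications other than myeloma for which lenalidomide/thalidomide are
    # dispensed: myelodysplastic syndromes, follicular/diffuse/peripheral-
    # cutaneous/other non-Hodgkin lymphoma, osteomyelofibrosis, acute
    # panmyelosis with myelofibrosis, POEMS (coded under its paraproteinaemia
    # neighbourhood), amyloidosis.
    exclusion_icd10: list[str] = [
        "D46*", "C82*", "C83*", "C84*", "C85*", "D474", "C944", "D472", "E85*",
    ]
    mm_specific_drugs: list[str] = [
        "L01XG01",  # bortezomib
        "L01XG02",  # carfilzomib
        "L01XG03",  # ixazomib
        "L01FC01",  # daratumumab
        "L01FX08",  # elotuzumab
        "L04AX06",  # pomalidomide
        "L01XX52",  # panobinostat-like example
    ]
    chemotherapy_drugs: list[str] = [
        "L01AA01",  # cyclophosphamide
        "L01AA03",  # melphalan
        "L01AA09",  # bendamustine
        "L01DB01",  # doxorubicin
        "L01CB01",  # etoposide
    ]
    lenalidomide_drugs: list[str] = ["L04AX04"]
    thalidomide_drugs: list[str] = ["L04AX02"]
    spep_procedures: list[str] = ["SPEP01"]
    upep_procedures: list[str] = ["UPEP01"]
    asct_procedures: list[str] = ["ASCT01"]

    @field_validator("mm_icd10", "exclusion_icd10")
    @classmethod
    def _nonempty_patterns(cls, v: list[str]) -> list[str]:
        if any(not p for p in v):
            raise ValueError("ICD-10 patterns must be non-empty")
        return [normalize_icd10(p) if not p.endswith("*") else normalize_icd10(p[:-1]) + "*" for p in v]

    # ------------------------------------------------------------------ drugs
    def drug_class_of(self, drug_id: str) -> str:
        if drug_id in self.mm_specific_drugs:
            return "mm_specific"
        if drug_id in self.lenalidomide_drugs:
            return "lenalidomide"
        if drug_id in self.thalidomide_drugs:
            return "thalidomide"
        if drug_id in self.chemotherapy_drugs:
            return "chemotherapy"
        return "other"

    def classify_drug_ids(self, drug_ids: pd.Series) -> pd.Series:
        """Vectorized drug_id → drug_class resolution (unknown → ``other``)."""
        mapping: dict[str, str] = {}
        for lst, cls in (
            (self.mm_specific_drugs, "mm_specific"),
            (self.lenalidomide_drugs, "lenalidomide"),
            (self.thalidomide_drugs, "thalidomide"),
            (self.chemotherapy_drugs, "chemotherapy"),
        ):
            for code in lst:
                mapping[code] = cls
        return drug_ids.map(mapping).fillna("other")

    # ------------------------------------------------------------- procedures
    def procedure_kind_of(self, procedure_code: str) -> str:
        if procedure_code in self.spep_procedures:
            return "SPEP"
        if procedure_code in self.upep_procedures:
            return "UPEP"
        if procedure_code in self.asct_procedures:
            return "ASCT"
        return "other"

    def classify_procedure_codes(self, codes: pd.Series) -> pd.Series:
        mapping: dict[str, str] = {}
        for lst, kind in (
            (self.spep_procedures, "SPEP"),
            (self.upep_procedures, "UPEP"),
            (self.asct_procedures, "ASCT"),
        ):
            for code in lst:
                mapping[code] = kind
        return codes.map(mapping).fillna("other")

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_yaml(cls, path) -> "CodeListConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
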