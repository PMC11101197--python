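"""Cohort construction for training, validation and test populations.

Defect-present cases are built by inserting each synthetic defect type
into each source (normal) study; the defect-absent population replicates
every normal study once per paired defect geometry, so that each absent
case carries the centroid of the location where its paired defect would
have been inserted (needed for channel shifting).  The study design uses
12 defect types in training/validation ({anterior, inferior} x {30, 60}
degrees x {10, 17.5, 25}% severity) and 18 in testing, where an
out-of-distribution 45-degree extent appears only in the test split.

With the study defaults this yields 2208 present + 736 absent = 2944
training cases, 240 validation-present cases, and 1098 absent + 954
present = 2052 test cases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .defect import (
    DefectSpec,
    STUDY_EXTENTS_DEG,
    STUDY_LOCATIONS,
    STUDY_SEVERITIES,
    STUDY_TEST_ONLY_EXTENT_DEG,
)

__all__ = ["CohortManifest", "defect_type_table", "enumerate_cohort"]


def defect_type_table(include_test_only_extent=False):
    """Ordered list of DefectSpec types (12, or 18 with the 45-deg extent)."""
    extents = sorted(STUDY_EXTENTS_DEG + ((STUDY_TEST_ONLY_EXTENT_DEG,)
                                          if include_test_only_extent else ()))
    return [
        DefectSpec(location=loc, extent_deg=ext, severity=sev)
        for loc, ext, sev in itertools.product(STUDY_LOCATIONS, extents, STUDY_SEVERITIES)
    ]


@dataclass
class CohortManifest:
    """Per-case records of one split.

    Each record is a dict with: case_id, split, study_id, label
    ('present'/'absent'), defect type index, and the DefectSpec whose
    geometry the case references (the inserted defect for present cases,
    the paired insertion location for absent cases).
    """

    split: str
    records: list = field(default_factory=list)

    @property
    def n_present(self):
        return sum(r["label"] == "present" for r in self.records)

    @property
    def n_absent(self):
        return sum(r["label"] == "absent" for r in self.records)

    @property
    def n_total(self):
        return len(self.records)

    @property
    def study_ids(self):
        return {r["study_id"] for r in self.records}

    def to_dataframe(self):
        rows = []
        for r in self.records:
            d = r["defect"]
            rows.append({
                "case_id": r["case_id"], "split": self.split,
                "study_id": r["study_id"], "label": r["label"],
                "type_id": r["type_id"], "location": d.location,
                "extent_deg": d.extent_deg, "severity": d.severity,
            })
        return pd.DataFrame(rows)


def _present_records(split, studies, types):
    recs = []
    for sid in studies:
        for t, spec in enumerate(types):
            recs.append({
                "case_id": f"{split}-p-{sid}-t{t:02d}", "study_id": sid,
                "label": "present", "type_id": t, "defect": spec,
            })
    return recs


def _absent_records(split, studies, paired_types):
    recs = []
    for sid in studies:
        for t, spec in paired_types:
            recs.append({
                "case_id": f"{split}-a-{sid}-t{t:02d}", "study_id": sid,
                "label": "absent", "type_id": t, "defect": spec,
            })
    return recs


def enumerate_cohort(
    n_normal_train=184,
    n_defect_types_train=12,
    n_locations_x_extents=4,
    n_val_present_sources=20,
    n_val_types=12,
    n_val_absent_sources=20,
    n_test_absent_sources=61,
    n_test_present_sources=53,
    n_test_types=18,
):
    """Enumerate the train/validation/test manifests.

    Closed-form sizes: train present = n_normal_train * n_defect_types_train,
    train absent = n_normal_train * n_locations_x_extents; validation
    present = n_val_present_sources * n_val_types; test absent/present =
    n_test_{absent,present}_sources * n_test_types.  Study ids never cross
    splits, and the 45-degree extent occurs only in the test type table.
    """
    for name, v in [("n_normal_train", n_normal_train),
                    ("n_defect_types_train", n_defect_types_train),
                    ("n_locations_x_extents", n_locations_x_extents),
                    ("n_val_present_sources", n_val_present_sources),
                    ("n_val_types", n_val_types),
                    ("n_test_absent_sources", n_test_absent_sources),
                    ("n_test_present_sources", n_test_present_sources),
                    ("n_test_types", n_test_types)]:
        if v < 1:
            raise ValueError(f"{name} must be positive")

    train_types_all = defect_type_table(include_test_only_extent=False)
    test_types_all = defect_type_table(include_test_only_extent=True)
    if n_defect_types_train > len(train_types_all):
        raise ValueError("n_defect_types_train exceeds the defect-type table")
    if n_val_types > len(train_types_all) or n_test_types > len(test_types_all):
        raise ValueError("requested type count exceeds the defect-type table")
    train_types = train_types_all[:n_defect_types_train]
    val_types = train_types_all[:n_val_types]
    test_types = test_types_all[:n_test_types]

    # one absent replicate per distinct (location, extent) geometry
    geometries = []
    for t, spec in enumerate(train_types):
        key = (spec.location, spec.extent_deg)
        if key not in [(s.location, s.extent_deg) for _, s in geometries]:
            geometries.append((t, spec))
    if len(geometries) < n_locations_x_extents:
        raise ValueError(
            f"defect-type table provides only {len(geometries)} distinct "
            f"location-extent geometries, but n_locations_x_extents="
            f"{n_locations_x_extents} replicates were requested")
    geometries = geometries[:n_locations_x_extents]

    train_studies = [f"tr{j:04d}" for j in range(n_normal_train)]
    val_p_studies = [f"vp{j:04d}" for j in range(n_val_present_sources)]
    val_a_studies = [f"va{j:04d}" for j in range(n_val_absent_sources)]
    test_a_studies = [f"sa{j:04d}" for j in range(n_test_absent_sources)]
    test_p_studies = [f"sp{j:04d}" for j in range(n_test_present_sources)]

    train = CohortManifest("train",
                           _present_records("train", train_studies, train_types)
                           + _absent_records("train", train_studies, geometries))
    val_geoms = [(t, s) for t, s in enumerate(val_types)]
    val = CohortManifest("validation",
                         _present_records("val", val_p_studies, val_types)
                         + _absent_records("val", val_a_studies, val_geoms))
    test_geoms = [(t, s) for t, s in enumerate(test_types)]
    test = CohortManifest("test",
                          _present_records("test", test_p_studies, test_types)
                          + _absent_records("test", test_a_studies, test_geoms))
    return train, val, test
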