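"""In silico knockouts: delete nodes, refit, rebuild the network, diff.

Deleting a level-1 variable removes its genotype column and mask row.
Deleting a level-2 group removes its mask column; level-1 variables left
without any annotation are regrouped into synthetic intergenic units (the
cascade is recorded, the variables themselves are kept so the level-1
design is preserved). The full loop is recorded as a replayable
:class:`PerturbationRecord` keyed to content hashes of its inputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import StaleRecordError, UsageError, ValidationError
from .grn import ConnectivityMode, GRNDiff, build_grn, diff_grn, layout_hint
from .io import (
    GRN,
    AnnotationMask,
    GenotypeDataset,
    _grn_from_dict,
    _grn_to_dict,
)
from .preprocess import assign_intergenic, build_group_features, standardize_columns
from .select import BackendConfig, get_backend

RECORD_SCHEMA_VERSION = 1


@dataclass
class Perturbation:
    """A set of node deletions, each tagged with its molecular level."""

    deleted: list[tuple[str, int]]
    note: str = ""
    timestamp: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.deleted:
            raise UsageError("perturbation deletes nothing")
        ids = [d[0] for d in self.deleted]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate ids in perturbation")
        for _, level in self.deleted:
            if level not in (1, 2):
                raise ValidationError("perturbation levels must be 1 or 2")
        if self.timestamp is None:
            self.timestamp = (
                datetime.datetime.now(datetime.timezone.utc).isoformat()
            )

    def to_dict(self) -> dict:
        return {
            "deleted": [{"id": i, "level": lv} for i, lv in self.deleted],
            "note": self.note,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Perturbation":
        return cls(
            deleted=[(e["id"], int(e["level"])) for e in d["deleted"]],
            note=d.get("note", ""),
            timestamp=d.get("timestamp"),
        )


@dataclass
class PerturbationRecord:
    """Provenance of one knockout-and-refit cycle."""

    perturbation: Perturbation
    before: GRN
    after: GRN
    diff: GRNDiff
    config: BackendConfig
    backend: str
    grn_params: dict
    cascaded_intergenic: list[str] = field(default_factory=list)
    converged: bool = True
    input_hashes: dict = field(default_factory=dict)
    input_paths: dict = field(default_factory=dict)
    package_version: str = ""

    def to_dict(self) -> dict:
        return {
            "schema_version": RECORD_SCHEMA_VERSION,
            "perturbation": self.perturbation.to_dict(),
            "before_grn": _grn_to_dict(self.before),
            "after_grn": _grn_to_dict(self.after),
            "diff": self.diff.to_dict(),
            "config": self.config.to_dict(),
            "backend": self.backend,
            "grn_params": self.grn_params,
            "cascaded_intergenic": self.cascaded_intergenic,
            "converged": self.converged,
            "input_hashes": self.input_hashes,
            "input_paths": self.input_paths,
            "package_version": self.package_version,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def apply_perturbation(
    data: GenotypeDataset, mask: AnnotationMask, p: Perturbation
) -> tuple[GenotypeDataset, AnnotationMask, list[str]]:
    """Propagate deletions into (X, M); returns the cascade group ids too."""
    del1 = [i for i, lv in p.deleted if lv == 1]
    del2 = [i for i, lv in p.deleted if lv == 2]
    unknown1 = [i for i in del1 if i not in data.variable_ids]
    if unknown1:
        raise ValidationError(f"unknown level-1 id(s): {unknown1}")
    unknown2 = [i for i in del2 if i not in mask.col_ids]
    if unknown2:
        raise ValidationError(f"unknown level-2 id(s): {unknown2}")
    if data.variable_ids != mask.row_ids:
        raise ValidationError("variable ids do not match mask row ids")

    keep_rows = [j for j, v in enumerate(data.variable_ids) if v not in set(del1)]
    if not keep_rows:
        raise ValidationError("perturbation would delete every level-1 variable")
    keep_cols = [g for g, c in enumerate(mask.col_ids) if c not in set(del2)]
    if not keep_cols:
        raise ValidationError("perturbation would delete every level-2 group")

    new_data = GenotypeDataset(
        sample_ids=list(data.sample_ids),
        variable_ids=[data.variable_ids[j] for j in keep_rows],
        X=data.X[:, keep_rows].copy(),
        y=None if data.y is None else data.y.copy(),
        covariates=None if data.covariates is None else data.covariates.copy(),
        covariate_names=(
            None if data.covariate_names is None else list(data.covariate_names)
        ),
        family=None if data.family is None else list(data.family),
    )
    new_mask = AnnotationMask(
        row_ids=[mask.row_ids[j] for j in keep_rows],
        col_ids=[mask.col_ids[g] for g in keep_cols],
        values=mask.values[np.ix_(keep_rows, keep_cols)].copy(),
    )
    new_mask, report = assign_intergenic(new_mask)
    return new_data, new_mask, report.intergenic_groups_created


def _grn_params_to_kwargs(grn_params: dict) -> dict:
    def mode(d: dict) -> ConnectivityMode:
        return ConnectivityMode(
            mode=d.get("mode", "none"), edge_threshold=d.get("edge_threshold")
        )

    return {
        "l1_cutoff": grn_params["l1_cutoff"],
        "l2_cutoff": grn_params["l2_cutoff"],
        "l1_mode": mode(grn_params.get("l1_connectivity", {"mode": "none"})),
        "l2_mode": mode(grn_params.get("l2_connectivity", {"mode": "none"})),
    }


def _fit_and_build(
    data: GenotypeDataset,
    mask: AnnotationMask,
    backend_name: str,
    config: BackendConfig,
    grn_params: dict,
) -> tuple[GRN, bool]:
    backend = get_backend(backend_name)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        result = backend(data, mask, config)
    kwargs = _grn_params_to_kwargs(grn_params)
    level_data = None
    needs = [
        lv
        for lv, m in ((1, kwargs["l1_mode"]), (2, kwargs["l2_mode"]))
        if m.mode == "sparse"
    ]
    if needs:
        level_data = {}
        if 1 in needs:
            level_data[1] = (standardize_columns(data.X), list(data.variable_ids))
        if 2 in needs:
            H, gids, _ = build_group_features(data, mask)
            level_data[2] = (H, gids)
    g = build_grn(result, mask, level_data=level_data, **kwargs)
    if grn_params.get("layout"):
        g = layout_hint(g, grn_params["layout"])
    return g, result.converged


def perturb_and_rerun(
    data: GenotypeDataset,
    mask: AnnotationMask,
    p: Perturbation,
    backend: str,
    config: BackendConfig,
    grn_params: dict,
    before: Optional[GRN] = None,
    input_paths: Optional[dict] = None,
) -> PerturbationRecord:
    """The full knockout loop: fit, delete, refit, rebuild, diff.

    ``grn_params`` carries l1_cutoff / l2_cutoff / l1_connectivity /
    l2_connectivity / layout exactly as stored in GRN metadata, so the
    rebuilt network uses the same settings as the original. A precomputed
    ``before`` GRN skips the initial fit.
    """
    conv_before = True
    if before is None:
        before, conv_before = _fit_and_build(data, mask, backend, config, grn_params)
    for nid, lv in p.deleted:
        present = nid in data.variable_ids if lv == 1 else nid in mask.col_ids
        if not present:
            raise ValidationError(f"cannot delete unknown id {nid!r} (level {lv})")
    new_data, new_mask, cascades = apply_perturbation(data, mask, p)
    after, conv_after = _fit_and_build(
        new_data, new_mask, backend, config, grn_params
    )
    deleted_ids = {i for i, _ in p.deleted}
    leaked = deleted_ids & set(after.node_ids())
    assert not leaked, f"deleted node(s) present in the after GRN: {leaked}"
    record = PerturbationRecord(
        perturbation=p,
        before=before,
        after=after,
        diff=diff_grn(before, after),
        config=config,
        backend=backend,
        grn_params=grn_params,
        cascaded_intergenic=cascades,
        converged=conv_before and conv_after,
        input_paths=dict(input_paths or {}),
    )
    if input_paths:
        record.input_hashes = {
            key: sha256_file(path) for key, path in input_paths.items()
        }
    return record


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def replay(record_path: str | Path) -> PerturbationRecord:
    """Re-execute a stored perturbation record and verify bit-identity.

    Re-reads the recorded input files (checked against their stored content
    hashes), reruns the knockout with the stored config, and asserts the
    regenerated after-GRN equals the stored one.
    """
    from . import __version__
    from .io import read_genotype_dataset, read_mask

    record_path = Path(record_path)
    with open(record_path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != RECORD_SCHEMA_VERSION:
        raise StaleRecordError(
            f"unsupported record schema_version {doc.get('schema_version')!r}"
        )
    paths = doc.get("input_paths", {})
    for key in ("x", "y", "mask"):
        if key not in paths:
            raise StaleRecordError(f"record lacks input path {key!r}")
    for key, path in paths.items():
        if not Path(path).exists():
            raise StaleRecordError(f"recorded input missing on disk: {path}")
        actual = sha256_file(path)
        if actual != doc["input_hashes"].get(key):
            raise StaleRecordError(
                f"input {key!r} changed since the record was written: {path}"
            )
    stored_version = doc.get("package_version", "")
    if stored_version and stored_version != __version__:
        warnings.warn(
            f"record written by version {stored_version}, replaying with "
            f"{__version__}; comparing outputs anyway",
            RuntimeWarning,
            stacklevel=2,
        )
    data = read_genotype_dataset(paths["x"], paths["y"], coding="dosage")
    mask = read_mask(paths["mask"])
    cfg = {k: v for k, v in doc["config"].items()}
    config = BackendConfig(**cfg)
    p = Perturbation.from_dict(doc["perturbation"])
    stored_before = _grn_from_dict(doc["before_grn"])
    record = perturb_and_rerun(
        data, mask, p, doc["backend"], config, doc["grn_params"],
        input_paths=paths,
    )
    stored_after = _grn_from_dict(doc["after_grn"])
    if record.after != stored_after:
        raise StaleRecordError(
            "replayed after-GRN differs from the stored one; inputs or code "
            "are inconsistent with the record"
        )
    if record.before != stored_before:
        raise StaleRecordError("replayed before-GRN differs from the stored one")
    record.package_version = __version__
    return record
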