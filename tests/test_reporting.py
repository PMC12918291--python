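"""Report assembly, the public/local privacy boundary, and federation."""

from __future__ import annotations

import json
from datetime import datetime, timezone

import numpy as np
import pytest

from dpqc import (
    ReportConfig,
    aggregate_nodes,
    build_report,
    builtin_checks,
    export_local,
    export_public,
    open_ledger,
    public_view,
    status_for,
)
from dpqc import CohortSpec, generate_cohort

CREATED = datetime(2025, 3, 2, 14, 30, 5, tzinfo=timezone.utc)


def small_report(dataset, seed=0, **config_kwargs):
    config_kwargs.setdefault("cap", 2.0)
    config = ReportConfig(**config_kwargs)
    return build_report(dataset, builtin_checks(), open_ledger(config.cap),
                        config, np.random.default_rng(seed),
                        created_at=CREATED, seed_tag=f"seed={seed}")


# --- statuses ---------------------------------------------------------------


@pytest.mark.parametrize("dp,expected", [
    (4.90, "ok"), (10.0, "ok"), (20.10, "warning"), (30.0, "warning"),
    (30.01, "error"), (96.80, "error"), (0.0, "ok"),
])
def test_status_thresholds(dp, expected):
    assert status_for(dp, 10.0, 30.0) == expected


def test_inverted_thresholds_rejected():
    with pytest.raises(ValueError):
        status_for(5.0, 30.0, 10.0)


# --- report building --------------------------------------------------------


def test_report_structure_on_default_cohort(default_cohort):
    rep = small_report(default_cohort)
    assert len(rep.entries) == 10  # 8 unstratified + 2 survival strata
    strata = [e.stratum for e in rep.entries if e.check_id == "accuracy-3"]
    assert sorted(strata) == ["female", "male"]
    assert rep.budget_consumed <= rep.budget_cap
    assert rep.budget_consumed == pytest.approx(1.9)  # 8×0.2 + 0.3


def test_huge_epsilon_report_equals_raw(default_cohort):
    rep = small_report(default_cohort, cap=1e12, default_epsilon=1e10,
                       epsilon_overrides={"accuracy-3": 1e10})
    for e in rep.entries:
        assert e.dp_percent == e.raw_percent


def test_fail_closed_when_cap_too_small(default_cohort):
    rep = small_report(default_cohort, cap=0.1)
    assert all(e.status == "error" and e.reason == "budget exhausted"
               and e.dp_percent is None for e in rep.entries)
    assert rep.budget_consumed == 0.0


def test_partial_budget_refuses_later_checks(default_cohort):
    # cap 0.5 affords the first two checks at 0.2 but not all nine
    rep = small_report(default_cohort, cap=0.5)
    refused = [e for e in rep.entries if e.reason == "budget exhausted"]
    disclosed = [e for e in rep.entries if e.dp_percent is not None]
    assert refused and disclosed
    assert rep.budget_consumed <= 0.5 + 1e-9


def test_statuses_derive_from_dp_values(default_cohort):
    rep = small_report(default_cohort)
    for e in rep.entries:
        if e.dp_percent is not None:
            assert e.status == status_for(e.dp_percent, 10.0, 30.0)


def test_empty_dataset_rejected():
    from dpqc import Dataset

    with pytest.raises(ValueError):
        small_report(Dataset())


def test_small_cohort_release_gate_blocks_report():
    tiny = generate_cohort(CohortSpec(n_patients=10, seed=0))
    with pytest.raises(ValueError, match="below the minimum"):
        small_report(tiny)
    # explicit opt-out for local experimentation
    rep = small_report(tiny, min_n=0)
    assert rep.entries


def test_suppression_applies_to_low_raw_counts(default_cohort):
    rep = small_report(default_cohort, suppress_below=10)
    by_id = {(e.check_id, e.stratum): e for e in rep.entries}
    acc1 = by_id[("accuracy-1", None)]  # raw numerator ~1 on this profile
    assert acc1.numerator < 10
    assert acc1.suppressed and acc1.dp_percent == 0.0


# --- public/local boundary --------------------------------------------------


def test_public_export_discloses_no_raw_material(default_cohort, tmp_path):
    """The public byte stream carries no raw counts, percentages or seeds."""
    rep = small_report(default_cohort, seed=123)
    blob = export_public(rep, tmp_path / "pub.json").read_text()
    for forbidden in ("raw_percent", "numerator", "denominator", "seed_tag",
                      "seed=123"):
        assert forbidden not in blob
    doc = json.loads(blob)
    raw_values = {e.raw_percent for e in rep.entries if e.raw_percent}
    dp_values = {e["dp_percent"] for e in doc["entries"]}
    # released values are the noised ones, not the raw ones
    assert not raw_values <= dp_values
    assert doc["created_at"] == "2025-03-02"  # truncated to the day


def test_local_export_keeps_raw_values(default_cohort, tmp_path):
    rep = small_report(default_cohort, seed=5)
    doc = json.loads(export_local(rep, tmp_path / "loc.json").read_text())
    assert doc["seed_tag"] == "seed=5"
    assert all("raw_percent" in e for e in doc["entries"])


def test_public_reexport_is_byte_identical(default_cohort, tmp_path):
    rep = small_report(default_cohort)
    a = export_public(rep, tmp_path / "a.json").read_bytes()
    b = export_public(rep, tmp_path / "b.json").read_bytes()
    assert a == b


def test_public_budget_matches_ledger(default_cohort):
    ledger = open_ledger(2.0)
    config = ReportConfig(cap=2.0)
    rep = build_report(default_cohort, builtin_checks(), ledger, config,
                       np.random.default_rng(0), created_at=CREATED)
    assert public_view(rep)["consumed"] == ledger.consumed


# --- federation -------------------------------------------------------------


def _write_node_reports(tmp_path, n_nodes=3):
    paths = []
    for i in range(n_nodes):
        ds = generate_cohort(CohortSpec(n_patients=200, seed=i))
        rep = small_report(ds, seed=100 + i)
        rep.node_id = f"node-{i + 1}"
        paths.append(export_public(rep, tmp_path / f"node{i + 1}.json"))
    return paths


def test_aggregate_three_nodes(tmp_path):
    view = aggregate_nodes(_write_node_reports(tmp_path))
    assert list(view.table.columns) == ["node-1", "node-2", "node-3"]
    assert ("completeness-1", "") in view.table.index
    assert ("accuracy-3", "female") in view.table.index
    assert view.errors == []


def test_single_node_view_equals_report(tmp_path):
    (path,) = _write_node_reports(tmp_path, n_nodes=1)
    view = aggregate_nodes([path])
    doc = json.loads(path.read_text())
    for e in doc["entries"]:
        key = (e["check_id"], e.get("stratum") or "")
        assert view.table.loc[key, "node-1"] == pytest.approx(e["dp_percent"])


def test_malformed_report_skipped_with_error(tmp_path):
    paths = _write_node_reports(tmp_path, n_nodes=2)
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    view = aggregate_nodes(paths + [bad])
    assert len(view.reports) == 2
    assert len(view.errors) == 1


def test_aggregator_refuses_local_reports(tmp_path):
    """The privacy boundary: files with raw material are rejected by schema."""
    ds = generate_cohort(CohortSpec(n_patients=100, seed=0))
    rep = small_report(ds)
    local_path = export_local(rep, tmp_path / "local.json")
    with pytest.raises(ValueError, match="no valid public reports"):
        aggregate_nodes([local_path])


def test_missing_check_is_absent_not_zero(tmp_path):
    paths = _write_node_reports(tmp_path, n_nodes=2)
    doc = json.loads(paths[0].read_text())
    doc["entries"] = [e for e in doc["entries"]
                      if e["check_id"] != "uniqueness-1"]
    paths[0].write_text(json.dumps(doc))
    view = aggregate_nodes(paths)
    cell = view.table.loc[("uniqueness-1", ""), "node-1"]
    assert np.isnan(cell)


# --- config -----------------------------------------------------------------


def test_config_from_file_requires_cap(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("default_epsilon: 0.2\n")
    with pytest.raises(ValueError, match="cap"):
        ReportConfig.from_file(p)
    p.write_text("cap: 2.0\nsuppress_below: 10\n")
    config = ReportConfig.from_file(p)
    assert config.cap == 2.0 and config.suppress_below == 10


def test_config_rejects_unknown_keys(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("cap: 2.0\nbogus: 1\n")
    with pytest.raises(ValueError, match="unknown config keys"):
        ReportConfig.from_file(p)
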