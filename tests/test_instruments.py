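"""Instrument selection, LD pruning and strength statistics."""

import itertools

import numpy as np
import pytest

from summarymr import instruments
from summarymr.instruments import (
    apply_proxies,
    build_panel,
    compute_pve,
    effective_ld,
    f_statistic,
    filter_significant,
    ld_prune,
)
from summarymr.types import LDMatrix, ValidationError


class TestFilterSignificant:
    def test_threshold_is_inclusive(self, make_record):
        records = [
            make_record("rs1", pvalue=1e-9),
            make_record("rs2", pvalue=6e-8),
            make_record("rs3", pvalue=5e-8),
        ]
        kept = filter_significant(records)
        assert [r.snp_id for r in kept] == ["rs1", "rs3"]

    def test_empty_input(self):
        assert filter_significant([]) == []

    def test_all_significant_is_identity(self, make_record):
        records = [make_record(f"rs{i}", pvalue=1e-10) for i in range(3)]
        assert filter_significant(records) == records

    def test_idempotent(self, make_record):
        records = [make_record(f"rs{i}", pvalue=p) for i, p in enumerate([1e-9, 0.5, 5e-8])]
        once = filter_significant(records)
        assert filter_significant(once) == once


def _corr(ids, pairs):
    n = len(ids)
    r = np.eye(n)
    idx = {s: i for i, s in enumerate(ids)}
    for a, b, v in pairs:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return LDMatrix(ids, r)


class TestLdPrune:
    def test_correlated_pair_keeps_stronger(self, make_record):
        records = [make_record("rs1", pvalue=1e-10), make_record("rs2", pvalue=1e-9)]
        ld = _corr(["rs1", "rs2"], [("rs1", "rs2", np.sqrt(0.5))])
        kept, log = ld_prune(records, ld)
        assert [r.snp_id for r in kept] == ["rs1"]
        discard = [e for e in log if e.action == "discarded"]
        assert discard[0].snp_id == "rs2" and "rs1" in discard[0].reason

    def test_independent_snps_all_retained(self, make_record):
        records = [make_record(f"rs{i}", pvalue=10 ** -(9 + i)) for i in range(3)]
        kept, _ = ld_prune(records, LDMatrix.identity([r.snp_id for r in records]))
        assert {r.snp_id for r in kept} == {r.snp_id for r in records}

    def test_matches_brute_force_on_block_ld(self, make_record):
        """Greedy strongest-first pruning equals the rank-minimal maximal
        independent set found by exhaustive enumeration."""
        rng = np.random.default_rng(42)
        ids = [f"rs{i}" for i in range(10)]
        # three LD blocks with strong internal correlation plus weak noise
        blocks = [ids[0:4], ids[4:7], ids[7:10]]
        r = np.eye(10)
        for block in blocks:
            for a, b in itertools.combinations(block, 2):
                i, j = ids.index(a), ids.index(b)
                r[i, j] = r[j, i] = rng.uniform(0.3, 0.9)
        # PSD repair: project to nearest correlation-like matrix
        w, v = np.linalg.eigh(r)
        r = v @ np.diag(np.clip(w, 1e-6, None)) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        ld = LDMatrix(ids, r)
        records = [make_record(s, pvalue=float(p)) for s, p in zip(ids, rng.uniform(1e-12, 1e-8, 10))]

        kept, _ = ld_prune(records, ld, r2_max=0.01)

        rank = sorted(range(10), key=lambda i: instruments._strength_key(records[i]))
        rank_of = {ids[i]: rank.index(i) for i in range(10)}

        def independent(subset):
            return all(ld.r2(a, b) < 0.01 for a, b in itertools.combinations(subset, 2))

        best = None
        for size in range(10, 0, -1):
            for combo in itertools.combinations(ids, size):
                if not independent(combo):
                    continue
                # maximality: no excluded SNP can be added
                if any(independent(list(combo) + [s]) for s in ids if s not in combo):
                    continue
                key = tuple(sorted(rank_of[s] for s in combo))
                if best is None or key < best[0]:
                    best = (key, set(combo))
        assert {r_.snp_id for r_ in kept} == best[1]

    def test_output_invariant_to_input_order(self, make_record):
        rng = np.random.default_rng(3)
        records = [make_record(f"rs{i}", pvalue=float(p)) for i, p in enumerate(rng.uniform(1e-12, 1e-8, 6))]
        ld = _corr(
            [r.snp_id for r in records],
            [("rs0", "rs1", 0.5), ("rs2", "rs3", -0.4), ("rs4", "rs5", 0.2)],
        )
        kept, _ = ld_prune(records, ld)
        shuffled = [records[i] for i in rng.permutation(6)]
        kept_shuffled, _ = ld_prune(shuffled, ld)
        assert kept == kept_shuffled

    def test_permissive_threshold_retains_everything(self, make_record):
        records = [make_record(f"rs{i}", pvalue=1e-9) for i in range(3)]
        ld = _corr([r.snp_id for r in records], [("rs0", "rs1", 0.99)])
        kept, _ = ld_prune(records, ld, r2_max=1 + 1e-9)
        assert len(kept) == 3

    def test_one_snp_survives_per_fully_correlated_block(self, make_record):
        records = [make_record(f"rs{i}", pvalue=10 ** -(9 + i)) for i in range(4)]
        ld = _corr(
            [r.snp_id for r in records],
            [("rs0", "rs1", 1.0), ("rs2", "rs3", 1.0)],
        )
        kept, _ = ld_prune(records, ld, r2_max=0.99)
        assert [r.snp_id for r in kept] == ["rs3", "rs1"]  # strongest of each block

    def test_selection_log_replays_to_output(self, make_record):
        rng = np.random.default_rng(11)
        records = [make_record(f"rs{i}", pvalue=float(p)) for i, p in enumerate(rng.uniform(1e-12, 1e-8, 8))]
        ld = _corr(
            [r.snp_id for r in records],
            [("rs0", "rs5", 0.6), ("rs1", "rs2", 0.9), ("rs3", "rs7", 0.4)],
        )
        kept, log = ld_prune(records, ld)
        replayed = [e.snp_id for e in log if e.action == "kept"]
        assert replayed == [r.snp_id for r in kept]
        accounted = {e.snp_id for e in log if e.action in ("kept", "discarded")}
        assert accounted == {r.snp_id for r in records}

    def test_snp_absent_from_ld_names_the_snp(self, make_record):
        records = [make_record("rs1"), make_record("rs_orphan")]
        with pytest.raises(ValidationError, match="rs_orphan"):
            ld_prune(records, LDMatrix.identity(["rs1"]))


class TestProxies:
    def test_proxy_substitutes_ld_row_and_is_logged(self, make_record):
        # rs_x has no LD entry; its proxy rs_y is strongly correlated with rs1
        records = [make_record("rs1", pvalue=1e-12), make_record("rs_x", pvalue=1e-9)]
        ld = _corr(["rs1", "rs_y"], [("rs1", "rs_y", 0.8)])
        kept, log = ld_prune(records, ld, proxies={"rs_x": ("rs_y", 0.48)})
        assert [r.snp_id for r in kept] == ["rs1"]
        proxied = [e for e in log if e.action == "proxied"]
        assert proxied[0].snp_id == "rs_x" and "rs_y" in proxied[0].reason

    def test_empty_proxy_table_is_identity(self, make_record):
        records = [make_record("rs1"), make_record("rs2", pvalue=1e-9)]
        ld = LDMatrix.identity(["rs1", "rs2"])
        out, resolver = apply_proxies(records, ld, {})
        assert out == records and resolver.substitutions == []

    def test_missing_proxy_is_error(self, make_record):
        records = [make_record("rs_x")]
        ld = LDMatrix.identity(["rs1"])
        with pytest.raises(ValidationError, match="rs_ghost"):
            apply_proxies(records, ld, {"rs_x": ("rs_ghost", 0.5)})

    def test_effective_ld_keeps_original_labels(self):
        ld = _corr(["rs1", "rs_y"], [("rs1", "rs_y", 0.8)])
        eff = effective_ld(["rs1", "rs_x"], ld, {"rs_x": ("rs_y", 0.48)})
        assert eff.snp_ids == ["rs1", "rs_x"]
        assert eff.r("rs1", "rs_x") == pytest.approx(0.8)


class TestStrength:
    def test_pve_zero_for_null_effect(self, make_record):
        assert compute_pve([make_record("rs1", beta=0.0)]) == 0.0

    def test_pve_closed_form(self, make_record):
        assert compute_pve([make_record("rs1", eaf=0.5, beta=0.1)]) == pytest.approx(0.005)

    def test_pve_additive_over_independent_snps(self, make_record):
        a = make_record("rs1", eaf=0.5, beta=0.1)
        b = make_record("rs2", eaf=0.2, beta=0.05)
        assert compute_pve([a, b]) == pytest.approx(compute_pve([a]) + compute_pve([b]))

    def test_pve_missing_eaf_names_snp(self, make_record):
        with pytest.raises(ValidationError, match="rs_noeaf"):
            compute_pve([make_record("rs_noeaf", eaf=None)])

    def test_f_statistic_zero_at_zero_pve(self):
        assert f_statistic(0.0, 1000, 5) == 0.0

    def test_f_statistic_value(self):
        assert f_statistic(0.01, 10_000, 10) == pytest.approx(10.090, abs=5e-4)

    def test_f_statistic_increases_with_n(self):
        values = [f_statistic(0.01, n, 10) for n in (5_000, 10_000, 20_000)]
        assert values == sorted(values) and values[0] < values[-1]

    @pytest.mark.parametrize("pve,n,k", [(1.0, 100, 5), (0.1, 6, 5), (0.1, 100, 0)])
    def test_f_statistic_domain_errors(self, pve, n, k):
        with pytest.raises(ValidationError):
            f_statistic(pve, n, k)


class TestBuildPanel:
    def test_panel_combines_filter_prune_and_strength(self, make_record):
        records = [
            make_record("rs1", pvalue=1e-12, eaf=0.5, beta=0.1),
            make_record("rs2", pvalue=1e-9, eaf=0.3, beta=0.08),
            make_record("rs3", pvalue=0.5),  # not genome-wide significant
        ]
        ld = _corr(["rs1", "rs2", "rs3"], [("rs1", "rs2", 0.9)])
        panel = build_panel("trait", records, ld, n_exposure=100_000)
        assert panel.snp_ids == ["rs1"]
        assert panel.pve == pytest.approx(0.005)
        assert panel.f_statistic == pytest.approx(
            f_statistic(panel.pve, 100_000, 1)
        )
        reasons = {e.snp_id: e for e in panel.selection_log}
        assert reasons["rs3"].action == "discarded"
        assert reasons["rs2"].action == "discarded"

    def test_binary_exposure_has_no_pve(self, make_record):
        records = [make_record("rs1", pvalue=1e-12)]
        panel = build_panel(
            "t2d", records, LDMatrix.identity(["rs1"]), binary_exposure=True, n_exposure=1e5
        )
        assert panel.pve is None and panel.f_statistic is None
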