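"""Adoption, revenue, cashflow ledger and IRR solver."""

import json

import numpy as np
import pytest

import agridiff as ag
from agridiff.economics import LedgerConsistencyError, MultipleIRRWarning


def irr_bruteforce(flows, r_max=50.0):
    """Independent oracle: fine-grid NPV sign scan plus local refinement.

    Scans rates from -99% upward on a uniform grid, locates the first
    sign change of NPV, then refines on two successively finer local
    grids.  Shares no code with the bisection solver under test.
    """
    flows = np.asarray(flows, dtype=float)
    t = np.arange(flows.size)

    def scan(lo, hi, n):
        rates = np.linspace(lo, hi, n)
        vals = ((1.0 + rates)[:, None] ** (-t) * flows).sum(axis=1)
        sign = np.sign(vals)
        idx = np.nonzero(sign[:-1] * sign[1:] <= 0)[0]
        if idx.size == 0:
            return None
        k = int(idx[0])
        return rates[k], rates[k + 1]

    bracket = scan(-0.9999, r_max, 200_001)
    if bracket is None:
        return None
    for _ in range(2):
        bracket = scan(bracket[0], bracket[1], 2_001)
    return 0.5 * (bracket[0] + bracket[1])


def random_single_sign_change_ledgers(n, seed):
    """Ledgers with one negative initial outlay then nonnegative inflows."""
    rng = np.random.default_rng(seed)
    ledgers = []
    for _ in range(n):
        periods = int(rng.integers(2, 9))
        flows = np.zeros(periods)
        flows[0] = -rng.uniform(50.0, 2_000.0)
        flows[1:] = rng.uniform(5.0, 800.0, size=periods - 1)
        ledgers.append(flows)
    return ledgers


class TestAdoptersAndRevenue:
    def test_adopter_count_examples(self):
        assert ag.adopters(10_000, 0.05478) == pytest.approx(547.8)
        assert ag.adopters(123.4, 0.0) == 0.0
        assert ag.adopters(321.0, 1.0) == 321.0

    def test_adopters_rejects_bad_rate(self):
        with pytest.raises(ValueError):
            ag.adopters(10, 1.5)
        with pytest.raises(ValueError):
            ag.adopters(-1, 0.5)

    def test_revenue_examples(self):
        assert ag.revenue(6_600.396, 0.05478, 1_177, 0.19) == pytest.approx(
            80_857.8, abs=0.5
        )
        assert ag.revenue(0.0, 0.05478, 1_177, 0.19) == 0.0
        assert ag.revenue(1.0, 1.0, 100.0, 0.5) == 50.0

    def test_revenue_is_vectorised(self):
        informed = np.array([0.0, 100.0, 200.0])
        out = ag.revenue(informed, 0.5, 10.0, 0.2)
        assert out == pytest.approx([0.0, 100.0, 200.0])


class TestLedger:
    def test_base_year_zero_outflow(self, base_ledger):
        # $30,000 production + $10,000 first campaign year
        assert base_ledger.cash_out[0] == 40_000.0
        assert base_ledger.cash_in[0] == 0.0

    def test_base_total_revenue(self, base_ledger):
        assert base_ledger.total_revenue == pytest.approx(448_494, abs=1.0)

    def test_cashflow_identity(self, base_ledger):
        assert np.array_equal(
            base_ledger.cashflow, base_ledger.cash_in - base_ledger.cash_out
        )

    def test_campaign_spending_recorded_in_year_spent(self, base_ledger, base_config):
        spending = np.array(base_config.campaign_schedule)
        adoption = base_config.adoption_cost_per_adopter_year * np.asarray(
            ag.simulate(base_config).adopters
        )
        assert base_ledger.cash_out[1:3] == pytest.approx(
            spending[1:3] + adoption[:2]
        )
        assert base_ledger.cash_out[3] == pytest.approx(adoption[2])

    def test_all_zero_scenario_gives_zero_ledger(self):
        cfg = ag.ScenarioConfig(
            population_size=100,
            initial_informed_fraction=0.0,
            sharing_rate=0.0,
            spend_efficiency=0.0,
            campaign_schedule=(0.0, 0.0, 0.0),
            adoption_rate=0.0,
            annual_income=0.0,
            income_gain=0.0,
            production_cost=0.0,
            adoption_cost_per_adopter_year=0.0,
        )
        ledger = ag.build_ledger(ag.simulate(cfg))
        assert np.all(ledger.cash_in == 0.0)
        assert np.all(ledger.cash_out == 0.0)

    def test_mismatched_config_rejected(self, base_trajectory, base_config):
        other = base_config.replace(production_cost=1.0)
        with pytest.raises(LedgerConsistencyError):
            ag.build_ledger(base_trajectory, other)

    def test_adoption_cost_revenue_ratio_constant(self, base_ledger, base_config):
        # both series are fixed multiples of I(t)
        spending = np.concatenate([np.array(base_config.campaign_schedule), [0.0]])
        adoption_costs = base_ledger.cash_out[1:] - spending[1:]
        ratio = adoption_costs / base_ledger.cash_in[1:]
        expected = base_config.adoption_cost_per_adopter_year / (
            base_config.annual_income * base_config.income_gain
        )
        assert ratio == pytest.approx(np.full_like(ratio, expected), rel=1e-12)


class TestNPV:
    def test_zero_rate_is_undiscounted_sum(self, base_ledger):
        assert ag.npv(0.0, base_ledger) == pytest.approx(base_ledger.cashflow.sum())

    def test_single_period_example(self):
        assert ag.npv(0.10, [-100.0, 110.0]) == pytest.approx(0.0, abs=1e-12)

    def test_rate_at_or_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            ag.npv(-1.0, [-100.0, 110.0])


class TestIRR:
    def test_single_period_return(self):
        assert ag.irr([-100.0, 110.0]) == pytest.approx(0.10, abs=1e-8)

    def test_base_cubic_example(self):
        # bisection on the cubic NPV of the base-style ledger
        rate = ag.irr([-40_000.0, 66_518.6, 131_468.9, 206_440.3])
        assert rate == pytest.approx(2.196, abs=1e-3)

    def test_base_ledger_self_consistency(self, base_ledger):
        rate = ag.irr(base_ledger)
        assert rate == pytest.approx(2.1964, abs=5e-4)
        assert abs(ag.npv(rate, base_ledger)) <= 1e-6 * abs(
            base_ledger.cashflow[0]
        )

    def test_no_sign_change_is_undefined(self):
        assert ag.irr([100.0, 10.0, 1.0]) is None
        assert ag.irr([-100.0, -10.0]) is None
        assert ag.irr([0.0, 0.0, 0.0]) is None

    def test_too_few_periods_rejected(self):
        with pytest.raises(ValueError):
            ag.irr([-100.0])

    def test_multiple_sign_changes_warns_and_returns_smallest_root(self):
        # -10 + 30u - 21u^2 in u = 1/(1+r): roots r = 42/(30 ± sqrt(60)) - 1,
        # i.e. r = 0.112702 and r = 0.887298; the smaller must be returned
        with pytest.warns(MultipleIRRWarning):
            rate = ag.irr([-10.0, 30.0, -21.0])
        assert rate == pytest.approx(0.112702, abs=1e-5)

    def test_scale_invariance(self, base_ledger):
        flows = base_ledger.cashflow
        assert ag.irr(flows * 1e-3) == pytest.approx(ag.irr(flows), rel=1e-9)
        assert ag.irr(flows * 1e4) == pytest.approx(ag.irr(flows), rel=1e-9)

    def test_matches_bruteforce_oracle_on_random_ledgers(self):
        for flows in random_single_sign_change_ledgers(120, seed=20260930):
            expected = irr_bruteforce(flows)
            got = ag.irr(flows)
            if expected is None:
                assert got is None or got > 50.0
            else:
                assert got == pytest.approx(expected, abs=1e-4)

    def test_vectorised_grid_matches_scalar(self):
        ledgers = random_single_sign_change_ledgers(60, seed=7)
        width = max(len(f) for f in ledgers)
        matrix = np.zeros((len(ledgers), width))
        for i, flows in enumerate(ledgers):  # trailing zeros leave NPV unchanged
            matrix[i, : len(flows)] = flows
        rates = ag.irr_grid(matrix)
        for flows, vec_rate in zip(ledgers, rates):
            scalar = ag.irr(flows)
            if scalar is None:
                assert np.isnan(vec_rate)
            else:
                assert vec_rate == pytest.approx(scalar, rel=1e-6, abs=1e-8)

    @pytest.mark.parametrize(
        "field, direction",
        [
            ("adoption_rate", +1),
            ("annual_income", +1),
            ("income_gain", +1),
            ("production_cost", -1),
        ],
    )
    def test_monotone_response_across_scenarios(self, base_config, field, direction):
        rates = []
        for factor in (0.5, 1.0, 2.0, 4.0):
            cfg = base_config.replace(
                **{field: getattr(base_config, field) * factor}
            )
            summary = ag.summarize(ag.simulate(cfg))
            rates.append(summary.irr)
        diffs = np.diff([direction * r for r in rates])
        assert np.all(diffs >= -1e-9)


class TestSummarize:
    def test_base_summary_values(self, base_summary):
        assert base_summary.total_cost == pytest.approx(84_066, abs=1.0)
        assert base_summary.total_revenue == pytest.approx(448_494, abs=1.0)
        assert round(base_summary.time_to_10pct, 1) == 1.6
        assert base_summary.adopters_at_10pct == 548
        assert base_summary.final_adopters == 975  # round(0.05478 * 17,807.15)

    def test_zero_rate_scenario(self):
        cfg = ag.ScenarioConfig(
            population_size=1_000,
            adoption_rate=0.0,
            annual_income=0.0,
        )
        summary = ag.summarize(ag.simulate(cfg))
        assert summary.total_revenue == 0.0
        assert summary.irr is None

    def test_summary_json_roundtrip(self, base_summary, tmp_path):
        path = tmp_path / "summary.json"
        base_summary.to_json(path)
        data = json.loads(path.read_text())
        assert set(data) == {
            "irr", "total_revenue", "total_cost",
            "time_to_10pct", "adopters_at_10pct", "final_adopters",
        }
        assert data["adopters_at_10pct"] == 548
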