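import pytest

import growthref as gr


@pytest.fixture
def toy_reference():
    """Two-knot reference with L=1, M 10->12, S=0.1 (hand-checkable)."""
    return gr.LMSReference(measure="weight", sex="male",
                           ages=[1.0, 2.0], L=[1.0, 1.0],
                           M=[10.0, 12.0], S=[0.1, 0.1], label="toy")


@pytest.fixture(scope="session")
def chart_pair():
    """Synthetic (standard, specialized) chart pair at the default offsets."""
    return gr.make_chart_pair({"weight": -1.2, "height": -1.5, "bmi": -0.5})


@pytest.fixture(scope="session")
def simulated(chart_pair):
    """A moderate seeded cohort drawn against the specialized chart."""
    std, spec = chart_pair
    config = gr.SimulationConfig(n=1500, seed=42)
    cohort, truth = gr.simulate_cohort(config, std, spec)
    return config, cohort, truth


@pytest.fixture
def cohort_file(tmp_path):
    """A small hand-written cohort file with one malformed row."""
    path = tmp_path / "cohort.csv"
    path.write_text(
        "id,sex,age_years,weight_kg,height_cm,l_thyroxine\n"
        "a,M,4.0,16.0,100.0,1\n"
        "b,F,17.9,50.0,160.0,0\n"
        "c,M,18.0,70.0,175.0,0\n"
        "d,F,25.0,60.0,165.0,1\n"
        "e,M,3.0,0,95.0,0\n"          # non-positive weight: rejected
    )
    return path
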