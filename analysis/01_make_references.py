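"""Build the synthetic (standard, specialized) growth-chart pair.

The standard chart is an analytic LMS reference (logistic-like median
curves over 0-18 y, L = 1, constant S per measure); the specialized chart
shifts each median down by a fixed SDS offset (weight -1.2, height -1.5,
BMI -0.5), emulating a condition-specific reference population that sits
below the general one.  Writes both charts as CSV reference tables under
results/references/.
"""

from pathlib import Path

import growthref as gr

OUT = Path(__file__).resolve().parents[1] / "results" / "references"
DELTA = {"weight": -1.2, "height": -1.5, "bmi": -0.5}


def main() -> None:
    std, spec = gr.make_chart_pair(DELTA)
    for chart, name in ((std, "standard"), (spec, "specialized")):
        d = OUT / name
        d.mkdir(parents=True, exist_ok=True)
        for measure in ("weight", "height", "bmi"):
            gr.write_lms_reference(
                d / f"{measure}.csv",
                [chart.get(measure, s) for s in ("female", "male")])
    for measure, delta in DELTA.items():
        ref = std.get(measure, "male")
        m_std = ref.interpolate(5.0)[1]
        m_spec = spec.get(measure, "male").interpolate(5.0)[1]
        print(f"{measure:>7}: median at age 5 (boys) {m_std:7.2f} standard "
              f"vs {m_spec:7.2f} specialized (offset {delta:+.1f} SDS)")
    print(f"wrote chart pair under {OUT}")


if __name__ == "__main__":
    main()
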