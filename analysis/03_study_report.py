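#!/usr/bin/env python
"""Full monitoring-statistics report on the 11-triathlete cohort.

Runs the statistics engine on the packaged individual-level study data:
reference statistics (TE, CV, SWC) per variable, PRE/POST paired
comparisons with 90% CIs and effect sizes per session, group
magnitude-based inference against the SWC, the heavy-vs-light RPE
contrast, and the per-athlete DFA alpha-1 change inferences.  Writes
results/report.csv, results/individuals.csv, results/report.json and a
dot-and-CI figure of the individual changes.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from warmuphrv import build_study_report, study_fixture

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def plot_individuals(report, swc, path):
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, session, title in zip(axes, ("light", "heavy"), ("A  light session", "B  heavy session")):
        rows = [ic for ic in report.individuals if ic.session == session]
        ys = range(len(rows))
        ax.axvspan(-swc, swc, color="gold", alpha=0.3, label="trivial zone (±SWC)")
        for y, ic in zip(ys, rows):
            ax.plot(ic.ci50, [y, y], color="steelblue")
            ax.plot(ic.delta, y, "o", color="steelblue")
        ax.axvline(0, color="gray", lw=0.5)
        ax.set_yticks(list(ys), [str(ic.participant) for ic in rows])
        ax.set_xlabel("change in DFA α1 (POST − PRE, 50% CI)")
        ax.set_title(title)
    axes[0].set_ylabel("athlete")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main():
    cohort = study_fixture()
    report = build_study_report(cohort)

    frame = report.report_frame()
    frame.to_csv(OUT / "report.csv", index=False)
    report.individuals_frame().to_csv(OUT / "individuals.csv", index=False)
    (OUT / "report.json").write_text(report.to_json())

    swc = report.reference["dfa_a1"].swc
    plot_individuals(report, swc, OUT / "individual_changes.png")

    cols = ["variable", "session", "mean_diff", "p_value", "effect_size",
            "effect_descriptor", "mbi_display", "mbi_descriptor"]
    print("Group PRE/POST comparisons with magnitude-based inference:")
    print(frame[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print()
    c = report.contrast
    print(
        f"RPE heavy vs light: p = {c.p_value:.4f}, r = {c.effect_size:.2f} "
        f"({c.test_used}, n = {c.n})"
    )
    heavy = frame[(frame.variable == "dfa_a1") & (frame.session == "heavy")].iloc[0]
    print()
    print(
        "Finding: the heavy session suppresses the warm-up scaling exponent "
        f"(mean change {heavy.mean_diff:+.2f}, p = {heavy.p_value:.3f}, "
        f"dz = {heavy.effect_size:.2f}, chances {heavy.mbi_display} -> "
        f"{heavy.mbi_descriptor}), while no other monitoring variable shows a "
        "substantial heavy-session change; after the light session only the "
        "jump/tap performance measures move, and they move upward."
    )


if __name__ == "__main__":
    main()
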