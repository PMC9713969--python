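#!/usr/bin/env python
"""End-to-end warm-up analysis on one synthetic 10-minute recording.

Builds a 10-minute RR recording with known fractal structure and a few
injected ectopic beats, then runs the full measurement pipeline exactly as
it is applied to real warm-up data: artifact correction, extraction of the
minute-7-to-8 analysis window, smoothness-priors detrending, DFA alpha-1
and mean heart rate.  Writes results/warmup_pipeline.json.
"""

import json
import sys
from pathlib import Path

from warmuphrv import (
    FractalRRSpec,
    PreprocessConfig,
    alpha1,
    detect_and_correct_artifacts,
    extract_segment,
    generate_fractal_rr,
    inject_artifacts,
    mean_heart_rate,
    smoothness_priors_detrend,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    # ~10 min at ~450 ms/beat (warm-up intensity): ~1330 beats
    spec = FractalRRSpec(target_alpha1=1.0, n_beats=1340, mean_rr=450, sd_rr=25, seed=SEED)
    clean = generate_fractal_rr(spec)
    recording, truth = inject_artifacts(clean, kinds=("ectopic",), rate=0.01, seed=SEED)
    cfg = PreprocessConfig()

    corrected, report = detect_and_correct_artifacts(recording, cfg)
    segment = extract_segment(corrected, cfg.segment_start_s, cfg.segment_end_s)
    detrended = smoothness_priors_detrend(segment, cfg.lambda_sp)
    result = alpha1(detrended)

    payload = {
        "target_alpha1": spec.target_alpha1,
        "injected_artifact_beats": len(truth),
        "percent_corrected": report.percent_corrected,
        "excluded": report.excluded,
        "segment_beats": segment.n_beats,
        "alpha1": result.alpha1,
        "mean_hr_bpm": mean_heart_rate(segment),
    }
    (OUT / "warmup_pipeline.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(json.dumps(payload, indent=2))
    print()
    print(
        f"Finding: from a contaminated 10-min recording the pipeline corrected "
        f"{report.percent_corrected:.1f}% of beats, kept the recording "
        f"(below the 5% exclusion threshold), and recovered alpha-1 = "
        f"{result.alpha1:.2f} against a target of {spec.target_alpha1:.1f} "
        f"from the {segment.n_beats}-beat minute-7-to-8 window."
    )


if __name__ == "__main__":
    main()
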