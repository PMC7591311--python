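"""Recompute the frozen outcome-model intercepts for the generator presets.

Solves, per preset and outcome, the intercept that makes the large-n
simulated prevalence hit the target survey marginal (stunting 26.5% / wasting
15.2% in the north-eastern preset; 14.6% / 9.2% in the capital preset).
The resulting constants are stored in ``nutrineq.synthetic``.

Run from the repository root:  python scripts/calibrate_presets.py
"""

from nutrineq.synthetic import calibrate_outcome_intercept, preset

TARGETS = {
    "ne_like": {"stunted": 0.265, "wasted": 0.152},
    "pp_like": {"stunted": 0.146, "wasted": 0.092},
}


def main():
    for name, targets in TARGETS.items():
        cfg = preset(name)
        print(f'    "{name}": {{', end="")
        parts = []
        for outcome, target in targets.items():
            b0 = calibrate_outcome_intercept(cfg, outcome, target)
            parts.append(f'"{outcome}": {b0:.4f}')
        print(", ".join(parts) + "},")


if __name__ == "__main__":
    main()
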