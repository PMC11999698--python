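#!/usr/bin/env python
"""Hyperpolarizing current steps under control and Kv+HCN block.

Relaxes the calibrated model to rest, injects -200 pA at the soma for
200 ms in both pharmacological conditions (the blocked cell is held at the
control resting potential, as in the recordings), and writes the somatic
traces and the step summary.

Finding: the control cell deflects only ~0.7 mV (input resistance
~3.5 MOhm); removing the Kv and HCN conductances increases the deflection
to ~8.8 mV (~44 MOhm), the electrotonic opening that makes dendritic
IPSPs visible at the soma.
"""

import os

import pandas as pd

from octosim.protocols import calibrated_reference, run_current_step

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "steps")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    rows = []
    for condition in ("control", "kv_hcn_block"):
        model, rest = calibrated_reference(condition)
        res = run_current_step(model, rest, amplitude_pa=-200.0, duration=200.0)
        pd.DataFrame({"t_ms": res.times, "v_soma_mv": res.soma_trace}).to_csv(
            os.path.join(OUT, f"step_{condition}.csv"), index=False
        )
        rows.append(
            {
                "condition": condition,
                "delta_vm_mv": res.delta_vm,
                "r_n_mohm": res.r_n,
                "holding_pa": model.holding_pa,
                "steady": res.steady,
            }
        )
        print(f"{condition:13s}: dVm {res.delta_vm:.3f} mV, "
              f"R_N {res.r_n:.2f} MOhm, holding {model.holding_pa:.0f} pA")
    pd.DataFrame(rows).to_csv(os.path.join(OUT, "step_summary.csv"), index=False)


if __name__ == "__main__":
    main()
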