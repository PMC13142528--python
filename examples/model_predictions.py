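"""Predicted BOLD responses from the four evidence-accumulation models.

Each model processes words as linear evidence accumulation toward a
recognition threshold (higher for low-frequency words); the predicted BOLD
response is the total area under the activation curves.  The table for
each model shows the total area per condition and frequency bin, and the
frequency effect (low-pair minus high-pair area) per presentation
condition is the signature that separates the models.
"""

from multiword.accumulation import (
    AccumulatorParams,
    ModelKind,
    frequency_effect,
    predict_bold_table,
)
from multiword.design import Condition

params = AccumulatorParams()
print(f"Parameters: slope {params.slope_s}/ms, thresholds "
      f"{params.theta_high} (high) / {params.theta_low} (low), "
      f"kappa {params.kappa}, window {params.window_ms:.0f} ms\n")

for kind in ModelKind:
    table = predict_bold_table(kind, params).pivot_table(
        index="condition", columns="freq_bin", values="total_area"
    ).loc[["ZERO", "ONE", "TWO_SEQ", "TWO_SIM"]]
    seq_fx = frequency_effect(kind, params, Condition.TWO_SEQ)
    sim_fx = frequency_effect(kind, params, Condition.TWO_SIM)
    print(f"--- {kind.value} ---")
    print(table.round(2))
    print(f"frequency effect: sequential {seq_fx:.2f}, "
          f"simultaneous {sim_fx:.2f}\n")

# Reading the numbers: the serial model leaves a positive but shrunken
# simultaneous frequency effect (word 2 is only partially processed); the
# limited-capacity parallel model abolishes it exactly (the interference-
# reduced slope reaches neither threshold); the unlimited parallel model
# predicts identical responses in both presentation conditions (rejected
# by behavior); the hybrid keeps equal per-word areas and a simultaneous
# total equal to the sequential total.
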