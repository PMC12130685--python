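#!/usr/bin/env python
"""Free-water fraction recovery for the bi-tensor diffusion model.

Noise-free two-shell signals (b = 1500/3000 s/mm^2, 98 directions) are
inverted exactly; at SNR 40 the Monte-Carlo bias of the free-water fraction
stays within +-0.05 across planted fractions 0.1, 0.25 and 0.5 (the mild
positive bias is the Rician noise floor pushing attenuated signals up).

Writes results/freewater_recovery.csv.
"""

from pathlib import Path

from glymap import workflows

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    err_f, err_d = workflows.fw_noise_free_recovery()
    print(f"noise-free: max |f error| = {err_f:.2e}, max tensor error = {err_d:.2e} mm^2/s")
    df = workflows.fw_recovery_bias(f_values=(0.1, 0.25, 0.5), snr=40.0,
                                    n_rep=200, seed=30)
    df.to_csv(OUT / "freewater_recovery.csv", index=False)
    print(df.to_string(index=False))
    print("\nwrote", OUT / "freewater_recovery.csv")


if __name__ == "__main__":
    main()
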