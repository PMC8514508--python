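"""Forward curves of the four prediction models for lake water.

Uses the lake-water parameter set (A = 1256 Bq m^-3, alpha = 0.62,
xi = 5.00, tau = 693 d) for the fractional diffusion model, a
two-exponential fit-like parameter set for the decay-function model,
and a physically parametrised sediment-exchange (Bulgakov) model, which
is exactly the alpha = 1/2 special case of the FDM.
"""

import numpy as np

from fraclake import (
    BulgakovParams,
    FDMParams,
    TDMParams,
    c_bulgakov_full,
    c_fdm,
    c_tdm,
    initial_concentration_estimate,
)

fdm = FDMParams.from_xi_tau(A=1256.0, alpha=0.62, xi=5.00, tau=693.0)
tdm = TDMParams(Q1=300.0, k1=8e-3, Q2=80.0, k2=4e-4)
bul = BulgakovParams(sigma_d=20000.0, h_w=10.0, K_d=200.0, D_E=1e-5)

print("137Cs activity concentration of lake water, Bq m^-3")
print(f"{'day':>7} {'FDM':>10} {'TDM':>10} {'Bulgakov':>10}")
for t in (0.0, 234.0, 693.0, 1981.0, 5000.0, 10000.0):
    print(f"{t:>7.0f} {c_fdm(t, fdm):>10.1f} {c_tdm(t, tdm):>10.1f} "
          f"{c_bulgakov_full(t, bul):>10.1f}")

print()
print("After ~2000 days the TDM falls exponentially while the FDM")
print("follows t^-0.62, so the FDM predicts a longer low-level tail.")

inv = initial_concentration_estimate(20000.0, 1e6, 1e7)
print()
print(f"Inventory-based initial concentration: 20 kBq/m^2 sediment "
      f"inventory over a 1 km^2 bottom diluted in 1e7 m^3 of water "
      f"-> {inv:.0f} Bq m^-3 (compare the FDM amplitude A = 1256).")
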