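"""Model sizes of the architecture family, closed form vs enumeration.

The closed form sums kernel*c_in*c_out + c_out over every convolution
(2*c_in*c_out + c_out for transposed convolutions); enumeration walks the
built model's parameter arrays.  The two must agree exactly.
"""

from sigunet import (
    SIGUNET_DEFAULT,
    SIGUNET_LIGHT_DEFAULT,
    UNET1D_DEFAULT,
    build_network,
    count_parameters,
)

for cfg in (SIGUNET_DEFAULT, SIGUNET_LIGHT_DEFAULT, UNET1D_DEFAULT):
    closed = count_parameters(cfg)
    enumerated = build_network(cfg).num_parameters()
    print(f"{cfg.variant:15s} m={cfg.m:3d} n={cfg.n:3d} depth={cfg.depth}  "
          f"closed-form {closed:>9,d}  enumerated {enumerated:>9,d}")

# sigunet lands in the 100k-300k weight range, sigunet_light in 60k-200k;
# the doubling-schedule unet1d baseline is an order of magnitude larger.
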