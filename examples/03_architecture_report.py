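"""Shape and parameter arithmetic for the two reference presets.

The closed-form oracles predict each layer's output side
(floor((n - 3)/2) + 1 for the 3x3 stride-2 unpadded convolutions) and the
exact learnable-parameter count; both are guaranteed to match the
instantiated networks.
"""

import zipaer as z

for name in ("zipaer2", "zipaer3"):
    spec = z.get_preset(name)
    sides = [spec.input_side]
    for _ in spec.channel_schedule:
        sides.append(z.conv_out_side(sides[-1]))
    lat = z.latent_shape(spec)
    n = z.count_parameters(spec)
    ratio = spec.input_channels * spec.input_side ** 2 / lat.n_elements
    print(f"{name}: sides {' -> '.join(map(str, sides))}, "
          f"latent ({lat.channels}, {lat.side}, {lat.side})")
    print(f"  parameters: {n:,} (~{round(n / 1e6)}M); "
          f"element-count compression {ratio:.0f}x")
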