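"""Channel layout of the insole sensor array.

Each sample carries 28 channels: 16 pressure sensors (8 per foot, three
discrete levels before preprocessing), a 3-axis accelerometer and a 3-axis
gyroscope per foot.  Rows are time stamps (one per 0.01 s), columns are
channels in the fixed order below.
"""

from __future__ import annotations

PRESSURE_CHANNELS = tuple(
    f"p{side}{i}" for side in ("l", "r") for i in range(1, 9)
)
ACCELERATION_CHANNELS = tuple(f"a{side}{ax}" for side in ("l", "r") for ax in "xyz")
ROTATION_CHANNELS = tuple(f"r{side}{ax}" for side in ("l", "r") for ax in "xyz")

CHANNELS = PRESSURE_CHANNELS + ACCELERATION_CHANNELS + ROTATION_CHANNELS

N_PRESSURE = len(PRESSURE_CHANNELS)       # 16
N_ACCELERATION = len(ACCELERATION_CHANNELS)  # 6
N_ROTATION = len(ROTATION_CHANNELS)       # 6
N_CHANNELS = len(CHANNELS)                # 28

PRE = slice(0, N_PRESSURE)
ACC = slice(N_PRESSURE, N_PRESSURE + N_ACCELERATION)
ROT = slice(N_PRESSURE + N_ACCELERATION, N_CHANNELS)

#: (name, slice, width) of the three modality blocks, in order.
BLOCKS = (
    ("pre", PRE, N_PRESSURE),
    ("acc", ACC, N_ACCELERATION),
    ("rot", ROT, N_ROTATION),
)

SAMPLE_PERIOD = 0.01  # seconds

assert N_PRESSURE + N_ACCELERATION + N_ROTATION == N_CHANNELS == 28
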