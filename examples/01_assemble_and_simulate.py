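"""Assemble a toy connectome on a hex lattice and simulate a contrast flash.

Builds the four-type motion-detector motif (photoreceptor -> fast excitatory
relay + slow inhibitory relay -> detector), tiles it over a radius-4 lattice,
and records the central detector's voltage during an ON disc flash.
"""

import numpy as np

from dmnet.connectome import tile
from dmnet.dynamics import SimConfig, simulate
from dmnet.fixtures import make_motion_motif
from dmnet.hexlattice import enumerate_hex
from dmnet.stimuli import circular_flash

motif = make_motion_motif(radius=4)
lattice = enumerate_hex(4)
network = tile(motif.spec, lattice)
print(f"lattice: {len(lattice)} columns (radius {lattice.radius})")
print(f"assembled: {network.n_neurons} neurons, {network.n_connections} connections")

detector = network.central_neuron("D")
cfg = SimConfig(dt=5.0, grey_warmup=1000.0, record=np.array([detector]))
stim = circular_flash(lattice, intensity=1.0, radius=3, dt=5.0)
trace = simulate(network, motif.params, stim, cfg)

v = trace.data[:, 0]
print(f"simulated {len(v)} steps of 5 ms; baseline V = {v[0]:+.4f} a.u.")
print(f"peak detector response during the flash: {v.max():+.4f} a.u.")
# The detector rests slightly below zero and transiently depolarizes when the
# ON disc appears; the peak voltage is what the tuning indices are built from.
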