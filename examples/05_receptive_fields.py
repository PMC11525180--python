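"""Receptive-field mapping with single-ommatidium flashes.

Flashes one column at a time, records the central detector, and assembles
the spatio-temporal receptive field (STRF), its spatial slice at the
response extremum (SRF) and the central time course (TRF).
"""

import numpy as np

from dmnet.connectome import tile
from dmnet.dynamics import SimConfig, simulate
from dmnet.fixtures import make_motion_motif
from dmnet.hexlattice import enumerate_hex
from dmnet.stimuli import ommatidium_flash
from dmnet.tuning import receptive_fields

motif = make_motion_motif(radius=3)
lattice = enumerate_hex(3)
network = tile(motif.spec, lattice)
detector = network.central_neuron("D")
cfg = SimConfig(dt=5.0, grey_warmup=1000.0, record=np.array([detector]))

offsets = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]
traces = []
for off in offsets:
    stim = ommatidium_flash(lattice, off, intensity=1.0, duration=20.0,
                            pre=500.0, post=1000.0, dt=5.0)
    traces.append(simulate(network, motif.params, stim, cfg).data[:, 0])

rf = receptive_fields(np.stack(traces), offsets, dt=5.0)
print("SRF (baseline-subtracted voltage at the central-flash extremum):")
for (u, v), val in zip(offsets, rf.srf):
    print(f"  column ({u:+d},{v:+d}): {val:+.4f} a.u.")
print(f"TRF peak {rf.trf.max():+.4f} at t = {rf.extremum_step * 5.0:.0f} ms")
# The centre column excites the detector through the fast relay; the (+1, 0)
# column is net inhibitory through the slow flank -- the spatial asymmetry
# that makes the cell direction selective.
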