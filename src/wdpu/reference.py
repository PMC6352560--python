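"""Published reference statistics for the two shipped compositions.

These are ensemble-averaged structural measurements (mean ± sd) reported for
equilibrated PCL75DL25 and PCL75LL25 nanoparticles from large-scale
molecular-dynamics simulation.  The package uses them as *calibration
targets* for the synthetic generator (tune the generator until the
independent descriptor implementation recovers the value), never as outputs.
"""

REPORTED = {
    "PCL75DL25": {
        "rg": 68.90,                 # Å, whole-assembly radius of gyration
        "eccentricity": 0.039,
        "end_to_end": 99.976,        # Å, mean per-chain end-to-end distance
        "hbond_total": 108,          # hydrogen bonds (3.0 Å / 30° criterion)
        "rdf_chain_peak": 17.75,     # Å, chain-centroid RDF global peak
        "rdf_pla_first_peak": 8.25,  # Å, PLA segment-centroid RDF first peak
    },
    "PCL75LL25": {
        "rg": 70.01,
        "eccentricity": 0.079,
        "end_to_end": 54.990,
        "hbond_total": 67.909,
        "rdf_chain_peak": 16.75,
        "rdf_pla_first_peak": 23.75,
    },
}
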