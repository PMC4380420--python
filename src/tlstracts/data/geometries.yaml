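# Assay geometry registry.  Signed distance d from the lesion along the
# direction of TLS is the canonical coordinate; coord_maps derive external
# positions as pos = slope * d + offset on closed d-intervals.
#
# THF-plasmid: abasic-site analog at URA3 ORF position 605 on a centromeric
# plasmid; 550 nt upstream and 1.7 kb downstream sequenced; the footprint of
# the construction oligonucleotide (20 nt before to 26 nt after the lesion)
# is excluded from analysis.  The URA3-ORF map runs opposite to the TLS
# direction (pos = 605 - d); its domain mirrors the positions the assay
# annotates (1..826).
#
# UV-chrV: UV photolesion at the TC dipyrimidine occupying chromosome V
# positions 116929-116930; 2.5 kb sequenced on each side.  Downstream
# coordinates enter the inserted LEU2 selectable-marker fragment 185 nt
# after the lesion, where positions switch to insert-relative "i" numbering.
THF-plasmid: &thf_geom
  lesion_label: "THF (abasic-site analog) at URA3 position 605"
  upstream_extent: 550
  downstream_extent: 1700
  excluded_intervals: [[-20, 26]]
  coord_maps:
    URA3-ORF:
      - {d_min: -221, d_max: 604, slope: -1, offset: 605, system: URA3-ORF}
THF-control: *thf_geom
THF-plasmid-msh2:
  lesion_label: "THF (abasic-site analog) at URA3 position 605 (msh2 background)"
  upstream_extent: 20
  downstream_extent: 220
  excluded_intervals: [[-20, 26]]
  coord_maps:
    URA3-ORF:
      - {d_min: -20, d_max: 220, slope: -1, offset: 605, system: URA3-ORF}
UV-chrV: &uv_geom
  lesion_label: "UV photolesion at the ura3-G764A TC dipyrimidine (chrV 116929-116930)"
  upstream_extent: 2500
  downstream_extent: 2500
  excluded_intervals: []
  coord_maps:
    chromosome-V:
      - {d_min: -2500, d_max: -1, slope: 1, offset: 116929, system: chrV}
      - {d_min: 1, d_max: 185, slope: 1, offset: 116930, system: chrV}
      - {d_min: 186, d_max: 2500, slope: 1, offset: -185, system: LEU2-insert, suffix: i}
UV-canr: *uv_geom
UV-chrV-rad30:
  lesion_label: "UV photolesion at the ura3-G764A TC dipyrimidine (rad30 background)"
  upstream_extent: 2500
  downstream_extent: 1100
  excluded_intervals: []
  coord_maps:
    chromosome-V:
      - {d_min: -2500, d_max: -1, slope: 1, offset: 116929, system: chrV}
      - {d_min: 1, d_max: 185, slope: 1, offset: 116930, system: chrV}
      - {d_min: 186, d_max: 1100, slope: 1, offset: -185, system: LEU2-insert, suffix: i}
UV-chrV-rev3:
  lesion_label: "UV photolesion at the ura3-G764A TC dipyrimidine (rev3 background)"
  upstream_extent: 2500
  downstream_extent: 1000
  excluded_intervals: []
  coord_maps:
    chromosome-V:
      - {d_min: -2500, d_max: -1, slope: 1, offset: 116929, system: chrV}
      - {d_min: 1, d_max: 185, slope: 1, offset: 116930, system: chrV}
      - {d_min: 186, d_max: 1000, slope: 1, offset: -185, system: LEU2-insert, suffix: i}
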