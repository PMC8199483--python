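# Structural regions of two GH-11 xylanases (right-hand fold nomenclature),
# residue numbers 1-based inclusive. Multi-interval regions are comma lists.
regions:
  NpXyn11A:
    Fingers: "4-62,76-95,199-216"
    Thumb: "137-167"
    Thumb loop: "149-155"
    Palm: "96-100,113-121,195-199"
    Palm loop: "102-113"
    Helix: "176-186"
    Helix loop: "187-194"
    Cord: "122-129"
    Loop B3-A5: "63-75"
  EvXyn11TS:
    Fingers: "4-53,63-78,179-191"
    Thumb: "117-147"
    Thumb loop: "130-135"
    Palm: "79-83,89-95,172-178"
    Palm loop: "84-88"
    Helix: "155-166"
    Helix loop: "167-171"
    Cord: "96-106"
    Loop B3-A5: "54-62"
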