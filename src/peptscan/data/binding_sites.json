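{
  "description": "Eleven transient C-Tpr binding sites on the CRM1-RanGTP-Snurportin export complex. Sites 1-9 lie on CRM1 (chain A, 42 residues total), sites 10-11 on Snurportin (chain C, 8 residues total). predicted_interfacial marks residues flagged by an external interfacial-residue predictor (21 residues); salt_bridge marks residues forming a salt bridge at a 3.2 A cutoff (19 residues). fully_conserved flags are not encoded in this fixture.",
  "sites": [
    {
      "site_id": 1,
      "chain_id": "A",
      "position_note": "Far side away from the Snurportin, on convex side",
      "residues": [
        {"seq": 112, "name": "LYS", "salt_bridge": true},
        {"seq": 113, "name": "THR"},
        {"seq": 115, "name": "SER", "predicted_interfacial": true},
        {"seq": 118, "name": "THR", "predicted_interfacial": true},
        {"seq": 121, "name": "GLU", "predicted_interfacial": true, "salt_bridge": true},
        {"seq": 122, "name": "LYS", "predicted_interfacial": true}
      ]
    },
    {
      "site_id": 2,
      "chain_id": "A",
      "position_note": "Far side away from the Snurportin, on convex side",
      "residues": [
        {"seq": 240, "name": "TYR"},
        {"seq": 243, "name": "GLU", "salt_bridge": true}
      ]
    },
    {
      "site_id": 3,
      "chain_id": "A",
      "position_note": "Far side away from the Snurportin, on convex side",
      "residues": [
        {"seq": 253, "name": "LYS", "predicted_interfacial": true, "salt_bridge": true},
        {"seq": 256, "name": "ASN", "predicted_interfacial": true},
        {"seq": 285, "name": "THR"},
        {"seq": 289, "name": "LEU"},
        {"seq": 292, "name": "MET"},
        {"seq": 293, "name": "GLN"}
      ]
    },
    {
      "site_id": 4,
      "chain_id": "A",
      "position_note": "Next to the RanGTP, concave side",
      "residues": [
        {"seq": 446, "name": "LYS", "predicted_interfacial": true, "salt_bridge": true},
        {"seq": 447, "name": "ASP", "predicted_interfacial": true},
        {"seq": 455, "name": "LYS", "salt_bridge": true}
      ]
    },
    {
      "site_id": 5,
      "chain_id": "A",
      "position_note": "Next to the Snurportin-NES binding site, on convex side",
      "residues": [
        {"seq": 477, "name": "THR", "predicted_interfacial": true},
        {"seq": 481, "name": "GLN", "predicted_interfacial": true},
        {"seq": 485, "name": "ASN"},
        {"seq": 515, "name": "ARG", "predicted_interfacial": true},
        {"seq": 522, "name": "LYS", "predicted_interfacial": true},
        {"seq": 523, "name": "ASP", "predicted_interfacial": true}
      ]
    },
    {
      "site_id": 6,
      "chain_id": "A",
      "position_note": "Near Snurportin, on the concave side",
      "residues": [
        {"seq": 556, "name": "ARG", "salt_bridge": true},
        {"seq": 593, "name": "GLN"},
        {"seq": 594, "name": "LYS"},
        {"seq": 596, "name": "ARG", "salt_bridge": true},
        {"seq": 597, "name": "ARG", "salt_bridge": true}
      ]
    },
    {
      "site_id": 7,
      "chain_id": "A",
      "position_note": "Immediately next to Snurportin on convex side",
      "residues": [
        {"seq": 675, "name": "ASN"},
        {"seq": 676, "name": "VAL", "predicted_interfacial": true},
        {"seq": 677, "name": "ASP", "salt_bridge": true},
        {"seq": 680, "name": "LYS"},
        {"seq": 681, "name": "ASP"},
        {"seq": 682, "name": "PRO"},
        {"seq": 726, "name": "GLU", "salt_bridge": true}
      ]
    },
    {
      "site_id": 8,
      "chain_id": "A",
      "position_note": "Far side away from Snurportin",
      "residues": [
        {"seq": 954, "name": "GLU", "predicted_interfacial": true, "salt_bridge": true},
        {"seq": 955, "name": "GLU", "predicted_interfacial": true, "salt_bridge": true},
        {"seq": 995, "name": "LYS", "predicted_interfacial": true},
        {"seq": 1047, "name": "GLU", "predicted_interfacial": true, "salt_bridge": true}
      ]
    },
    {
      "site_id": 9,
      "chain_id": "A",
      "position_note": "Next to RanGTP, concave side, away from Snurportin; blocked by helix H20B in absence of RanGTP",
      "residues": [
        {"seq": 1007, "name": "ASP", "salt_bridge": true},
        {"seq": 1012, "name": "LYS"},
        {"seq": 1013, "name": "GLU"}
      ]
    },
    {
      "site_id": 10,
      "chain_id": "C",
      "position_note": "Side of Snurportin near convex side",
      "residues": [
        {"seq": 55, "name": "ARG", "predicted_interfacial": true, "salt_bridge": true, "snurportin": true},
        {"seq": 92, "name": "LYS", "salt_bridge": true, "snurportin": true}
      ]
    },
    {
      "site_id": 11,
      "chain_id": "C",
      "position_note": "Far edge of Snurportin",
      "residues": [
        {"seq": 42, "name": "GLU", "predicted_interfacial": true, "salt_bridge": true, "snurportin": true},
        {"seq": 46, "name": "ARG", "predicted_interfacial": true, "snurportin": true},
        {"seq": 110, "name": "ASP", "salt_bridge": true, "snurportin": true},
        {"seq": 111, "name": "VAL", "snurportin": true},
        {"seq": 112, "name": "PRO", "snurportin": true},
        {"seq": 113, "name": "SER", "snurportin": true}
      ]
    }
  ]
}
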