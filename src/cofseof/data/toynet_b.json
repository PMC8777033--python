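{
    "compartments": {
        "c": "",
        "e": ""
    },
    "genes": [],
    "id": "toynet_b",
    "metabolites": [
        {
            "compartment": "e",
            "id": "glc_e",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "glc_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "A_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "B_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "P_c",
            "name": ""
        },
        {
            "compartment": "e",
            "id": "P_e",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "Q_c",
            "name": ""
        },
        {
            "compartment": "e",
            "id": "Q_e",
            "name": ""
        }
    ],
    "reactions": [
        {
            "gene_reaction_rule": "",
            "id": "EX_glc_e",
            "lower_bound": -10.0,
            "metabolites": {
                "glc_e": -1
            },
            "name": "",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "",
            "id": "T_glc",
            "lower_bound": 0.0,
            "metabolites": {
                "glc_c": 1,
                "glc_e": -1
            },
            "name": "",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "",
            "id": "R1",
            "lower_bound": 0.0,
            "metabolites": {
                "A_c": 2,
                "glc_c": -1
            },
            "name": "",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "",
            "id": "R2",
            "lower_bound": 0.0,
            "metabolites": {
                "A_c": -1,
                "B_c": 1
            },
            "name": "",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "",
            "id": "BIOMASS",
            "lower_bound": 0.0,
            "metabolites": {
                "B_c": -1
            },
            "name": "",
            "objective_coefficient": 1.0,
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "",
            "id": "T_P",
            "lower_bound": 0.0,
            "metabolites": {
                "P_c": -1,
                "P_e": 1
            },
            "name": "",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "",
            "id": "EX_P_e",
            "lower_bound": 0.0,
            "metabolites": {
                "P_e": -1
            },
            "name": "",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "",
            "id": "R5",
            "lower_bound": 0.0,
            "metabolites": {
                "A_c": -1,
                "P_c": 1,
                "Q_c": 1
            },
            "name": "",
            "upper_bound": 12.0
        },
        {
            "gene_reaction_rule": "",
            "id": "T_Q",
            "lower_bound": 0.0,
            "metabolites": {
                "Q_c": -1,
                "Q_e": 1
            },
            "name": "",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "",
            "id": "EX_Q_e",
            "lower_bound": 0.0,
            "metabolites": {
                "Q_e": -1
            },
            "name": "",
            "upper_bound": 1000.0
        }
    ],
    "version": "1"
}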