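antigen,expected_cell_type,cell_type_analyzed
CD103,intestinal intraepithelial lymphocytes (IEL),False
CD41b,platelets,False
PAC-1,platelets,False
CD1a,"cortical thymocytes, dendritic cells and Langerhans cells; DOES NOT react with PBMCs",False
CD209,"dendritic cells, vascular endothelial cells",False
CD150,"T cells, B cells, thymocytes, germinal center and dendritic cells",True
CD16b,neutrophils,True
FMC7,B lymphocytes,True
CD197,lymphocytes,True
CD129,"low levels on eosinophils, mast cells, macrophages, B lymphocytes, T lymphocytes, and erythroid progenitors",True
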