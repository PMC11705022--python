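# Food-database column dictionary

CSV, UTF-8, one header row; an empty cell means "missing". One row per
product per time point.

| column          | type   | required | description                                              |
|-----------------|--------|----------|----------------------------------------------------------|
| product_code    | string | yes      | UPC when available, otherwise retailer-specific ID        |
| retailer_id     | string | yes      | retailer identifier                                       |
| brand           | string | no       | brand name (free text)                                    |
| brand_type      | enum   | no       | private_label_premium \| private_label_discount \| multinational \| domestic_or_other |
| tra_category    | letter | yes      | TRA major food category A–X (W, X excluded downstream)    |
| container_size  | number | yes      | net container size                                        |
| container_unit  | g\|ml  | no (g)   | unit for container_size                                   |
| serving_size    | number | no       | labelled serving size                                     |
| serving_unit    | g\|ml  | no       | unit for serving_size (must agree with container_unit)    |
| price           | number | no       | undiscounted shelf price, currency units                  |
| energy_kcal     | number | no       | energy per serving, kcal                                  |
| fat_g           | number | no       | total fat per serving, g                                  |
| satfat_g        | number | no       | saturated fat per serving, g                              |
| carb_g          | number | no       | carbohydrate per serving, g                               |
| sugars_g        | number | no       | total sugars per serving, g                               |
| fibre_g         | number | no       | dietary fibre per serving, g                              |
| protein_g       | number | no       | protein per serving, g                                    |
| sodium_mg       | number | no       | sodium per serving, mg                                    |
| calcium_mg      | number | no       | calcium per serving, mg                                   |
| fvnl_percent    | number | no       | fruit/vegetable/nut/legume content, % (0–100)             |

Prices are normalized per 100 g (or ml) with the **container** size as
basis; nutrients with the **serving** size.
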