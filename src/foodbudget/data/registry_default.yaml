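# Illustrative ECOICOP 5-digit food-group registry (62 groups).
#
# The exact national group list and its ten-category assignment depend on
# the licensed survey data and are user-supplied for a faithful run; this
# shipped default is an illustrative stand-in with the same structure:
# 62 groups, of which alcoholic beverages and baby food are excluded,
# leaving the 60 groups the model runs on.
groups:
  - {code: "01.1.1.1", name: "Rice", category: carbohydrate_rich}
  - {code: "01.1.1.2", name: "Bread", category: carbohydrate_rich}
  - {code: "01.1.1.3", name: "Other bakery products", category: carbohydrate_rich}
  - {code: "01.1.1.4", name: "Pizza and quiche", category: carbohydrate_rich}
  - {code: "01.1.1.5", name: "Pasta products and couscous", category: carbohydrate_rich}
  - {code: "01.1.1.6", name: "Breakfast cereals", category: carbohydrate_rich}
  - {code: "01.1.1.7", name: "Other cereal products", category: carbohydrate_rich}
  - {code: "01.1.1.8", name: "Flours and other cereals", category: carbohydrate_rich}
  - {code: "01.1.2.1", name: "Beef and veal", category: meat}
  - {code: "01.1.2.2", name: "Pork", category: meat}
  - {code: "01.1.2.3", name: "Lamb and goat", category: meat}
  - {code: "01.1.2.4", name: "Poultry", category: meat}
  - {code: "01.1.2.5", name: "Sausages and cured meat", category: meat}
  - {code: "01.1.2.6", name: "Other preserved or processed meat", category: meat}
  - {code: "01.1.2.7", name: "Edible offal", category: meat}
  - {code: "01.1.3.1", name: "Fresh or chilled fish", category: fish}
  - {code: "01.1.3.2", name: "Frozen fish", category: fish}
  - {code: "01.1.3.3", name: "Fresh or frozen seafood", category: fish}
  - {code: "01.1.3.4", name: "Preserved or processed fish and seafood", category: fish}
  - {code: "01.1.4.1", name: "Whole milk", category: dairy}
  - {code: "01.1.4.2", name: "Low-fat milk", category: dairy}
  - {code: "01.1.4.3", name: "Preserved milk", category: dairy}
  - {code: "01.1.4.4", name: "Yoghurt", category: dairy}
  - {code: "01.1.4.5", name: "Cheese and curd", category: dairy}
  - {code: "01.1.4.6", name: "Other milk products", category: dairy}
  - {code: "01.1.4.7", name: "Eggs", category: eggs}
  - {code: "01.1.5.1", name: "Butter", category: oils_fats}
  - {code: "01.1.5.2", name: "Margarine and other vegetable fats", category: oils_fats}
  - {code: "01.1.5.3", name: "Olive oil", category: oils_fats}
  - {code: "01.1.5.4", name: "Other edible oils", category: oils_fats}
  - {code: "01.1.6.1", name: "Citrus fruits", category: fruits}
  - {code: "01.1.6.2", name: "Bananas", category: fruits}
  - {code: "01.1.6.3", name: "Apples and pears", category: fruits}
  - {code: "01.1.6.4", name: "Stone fruits", category: fruits}
  - {code: "01.1.6.5", name: "Berries", category: fruits}
  - {code: "01.1.6.6", name: "Other fruits, nuts and dried fruit", category: fruits}
  - {code: "01.1.7.1", name: "Leaf and stem vegetables", category: vegetables}
  - {code: "01.1.7.2", name: "Cabbages", category: vegetables}
  - {code: "01.1.7.3", name: "Fruit vegetables", category: vegetables}
  - {code: "01.1.7.4", name: "Root crops and bulb vegetables", category: vegetables}
  - {code: "01.1.7.5", name: "Dried vegetables and pulses", category: vegetables}
  - {code: "01.1.7.6", name: "Preserved or processed vegetables", category: vegetables}
  - {code: "01.1.7.7", name: "Potatoes", category: carbohydrate_rich}
  - {code: "01.1.7.8", name: "Potato products", category: carbohydrate_rich}
  - {code: "01.1.7.9", name: "Other tubers and products of tuber vegetables", category: carbohydrate_rich}
  - {code: "01.1.8.1", name: "Sugar", category: sweets_snacks}
  - {code: "01.1.8.2", name: "Jams, marmalades and honey", category: sweets_snacks}
  - {code: "01.1.8.3", name: "Chocolate", category: sweets_snacks}
  - {code: "01.1.8.4", name: "Confectionery products", category: sweets_snacks}
  - {code: "01.1.8.5", name: "Edible ices and ice cream", category: sweets_snacks}
  - {code: "01.1.9.1", name: "Sauces and condiments", category: others}
  - {code: "01.1.9.2", name: "Salt, spices and culinary herbs", category: others}
  - {code: "01.1.9.3", name: "Baby food", category: others}
  - {code: "01.1.9.4", name: "Ready-made meals", category: others}
  - {code: "01.1.9.9", name: "Salty snacks and other food products n.e.c.", category: sweets_snacks}
  - {code: "01.2.1.1", name: "Coffee", category: others}
  - {code: "01.2.1.2", name: "Tea", category: others}
  - {code: "01.2.1.3", name: "Cocoa and powdered chocolate", category: others}
  - {code: "01.2.2.1", name: "Mineral or spring waters", category: others}
  - {code: "01.2.2.2", name: "Soft drinks", category: others}
  - {code: "01.2.2.3", name: "Fruit and vegetable juices", category: others}
  - {code: "02.1.0.0", name: "Alcoholic beverages", category: others}
exclusions:
  - "02.1.0.0"   # alcoholic beverages: out of scope for a reference budget
  - "01.1.9.3"   # baby food: out of scope for an adult reference person
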